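"""Attention-layer interpretation: averaged profiles and localization.

The attention vector assigns one weight per pooled position (t positions,
75 at full scale).  To see whether the model attends to the labeled
central core of the input — the region whose peak overlap defined the
labels — sequences are grouped by whether the model predicts any task
bound, the per-group mean attention profile is computed, and the mean
attention per pooled bin inside the core region is compared with the mean
outside it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .network import ModelConfig


@dataclass
class AttentionProfile:
    """Mean attention profile of a group of sequences."""

    group: str  # "predicted_none" | "predicted_any"
    mean_scores: np.ndarray | None  # length t; None when the group is empty
    n_sequences: int

    @property
    def empty(self) -> bool:
        return self.n_sequences == 0


def extract_attention(model, X: np.ndarray) -> np.ndarray:
    """Attention vectors for each sequence, shape (n, t); rows sum to 1."""
    return model.attention_vectors(X)


def group_profiles(attention: np.ndarray, predictions: np.ndarray,
                   threshold: float = 0.5
                   ) -> tuple[AttentionProfile, AttentionProfile]:
    """Split sequences by predicted binding and average their attention.

    A sequence belongs to *predicted_any* iff its maximum per-task
    probability exceeds ``threshold``, else to *predicted_none*.  Returns
    ``(none_profile, any_profile)``; an empty group yields a profile with
    ``n_sequences == 0`` and ``mean_scores is None``.
    """
    attention = np.asarray(attention)
    predictions = np.asarray(predictions)
    if len(attention) != len(predictions):
        raise ValueError("attention and predictions length mismatch")
    any_mask = predictions.max(axis=1) > threshold
    profiles = []
    for group, mask in (("predicted_none", ~any_mask), ("predicted_any", any_mask)):
        n = int(mask.sum())
        mean = attention[mask].mean(axis=0) if n else None
        profiles.append(AttentionProfile(group=group, mean_scores=mean,
                                         n_sequences=n))
    return profiles[0], profiles[1]


def core_bins(config: ModelConfig,
              core_span: tuple[int, int] = (400, 600)) -> np.ndarray:
    """Pooled-bin indices overlapping the core span of the input.

    Pooled bin j aggregates the conv windows starting at input positions
    [w*j, w*j + w); a bin is a core bin iff that start range intersects
    ``core_span``.  With full-scale pooling (w=13) and the default 200 bp
    core this yields bins 30..46.  (Each conv window additionally extends
    l - 1 bases to the right of its start; that receptive-field overhang
    is documented in the run manifest rather than widening the core set.)
    """
    w, t = config.pool_window, config.pooled_length
    s, e = core_span
    js = np.arange(t)
    lo = w * js
    hi = w * js + w
    return js[(lo < e) & (hi > s)]


def central_enrichment(profile: AttentionProfile,
                       core: np.ndarray | None = None,
                       config: ModelConfig | None = None,
                       core_span: tuple[int, int] = (400, 600)) -> float:
    """Mean attention per bin inside the core over the mean outside.

    ``core`` may be given directly as bin indices; otherwise it is derived
    from ``config`` and ``core_span``.  A uniform profile gives 1.0; all
    mass inside the core gives +inf.
    """
    if profile.empty or profile.mean_scores is None:
        raise ValueError("cannot compute enrichment of an empty profile")
    scores = np.asarray(profile.mean_scores, dtype=float)
    t = len(scores)
    if core is None:
        if config is None:
            raise ValueError("need either explicit core bins or a config")
        core = core_bins(config, core_span)
    core = np.asarray(core)
    if core.size == 0 or core.size >= t:
        raise ValueError("core bins must be a non-empty proper subset")
    mask = np.zeros(t, dtype=bool)
    mask[core] = True
    inside = scores[mask].mean()
    outside = scores[~mask].mean()
    if outside == 0:
        return float("inf")
    return float(inside / outside)


def attention_report(model, X: np.ndarray, threshold: float = 0.5,
                     core_span: tuple[int, int] = (400, 600),
                     use_true_labels: np.ndarray | None = None
                     ) -> dict:
    """Full interpretation pass: vectors, grouped profiles, enrichments.

    By default groups follow the model's predictions; pass binary labels
    via ``use_true_labels`` to group by ground truth instead.
    """
    att = extract_attention(model, X)
    if use_true_labels is not None:
        preds = np.asarray(use_true_labels, dtype=float)
    else:
        preds = model.predict_proba(X)
    none_p, any_p = group_profiles(att, preds, threshold)
    core = core_bins(model.config_, core_span)
    out = {"attention": att, "predicted_none": none_p, "predicted_any": any_p,
           "core_bins": core}
    for key, prof in (("enrichment_none", none_p), ("enrichment_any", any_p)):
        out[key] = (central_enrichment(prof, core=core)
                    if not prof.empty else float("nan"))
    return out


def profiles_frame(none_p: AttentionProfile, any_p: AttentionProfile
                   ) -> pd.DataFrame:
    """Tidy per-bin table of the two mean profiles (for TSV export)."""
    rows = []
    for prof in (none_p, any_p):
        if prof.empty:
            continue
        for j, v in enumerate(prof.mean_scores):
            rows.append({"group": prof.group, "bin": j, "mean_attention": v,
                         "n_sequences": prof.n_sequences})
    return pd.DataFrame(rows)
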