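"""Motif extraction from trained convolution kernels.

After training, each kernel acts as a motif scanner.  For every input
sequence and kernel, the l-long subsequence under the position of highest
pre-pooling ReLU activation is harvested (only when that maximum is
strictly positive); the per-kernel site collections are summarized as
position probability matrices (PPMs), exported in MEME minimal motif
format for downstream motif-comparison tools (e.g. TOMTOM), and
deduplicated by complete-linkage clustering of consensus-sequence
Levenshtein distances.

Internally PPM columns follow the package-wide A,G,C,T order; the MEME
writer emits the format's required A,C,G,T column order.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from . import network
from .seq_data import ALPHABET, one_hot_decode

_AGCT_TO_ACGT = [0, 2, 1, 3]  # column permutation (involution)

DEFAULT_THRESHOLDS = (0, 3, 5, 10)
DEFAULT_MIN_SITES = 10


@dataclass
class Motif:
    """A harvested kernel motif.

    ``ppm`` is an l x 4 row-stochastic matrix (columns A,G,C,T);
    ``consensus`` is the per-position argmax base, ties broken toward the
    first base in A,C,G,T alphabetical order; ``low_support`` flags motifs
    built from fewer than the minimum site count.
    """

    kernel_id: int
    ppm: np.ndarray
    n_sites: int
    low_support: bool = False

    @property
    def length(self) -> int:
        return self.ppm.shape[0]

    @property
    def consensus(self) -> str:
        acgt = self.ppm[:, _AGCT_TO_ACGT]
        return "".join("ACGT"[int(j)] for j in np.argmax(acgt, axis=1))


@dataclass
class MotifClustering:
    """Result of edit-distance deduplication across thresholds."""

    motifs: list[Motif]
    linkage_matrix: np.ndarray | None  # scipy linkage record (None for n=1)
    assignments: dict[int, np.ndarray]  # threshold d -> cluster label per motif
    distinct_count: dict[int, int]  # threshold d -> number of clusters

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "kernel_id": [m.kernel_id for m in self.motifs],
            "consensus": [m.consensus for m in self.motifs],
            "n_sites": [m.n_sites for m in self.motifs],
        })
        for d, labels in self.assignments.items():
            df[f"cluster@d={d}"] = labels
        return df

    def merges_frame(self) -> pd.DataFrame:
        """Dendrogram merge list (step, left, right, height) for plotting."""
        if self.linkage_matrix is None:
            return pd.DataFrame(columns=["step", "left", "right", "height"])
        Z = self.linkage_matrix
        return pd.DataFrame({
            "step": np.arange(len(Z)),
            "left": Z[:, 0].astype(int),
            "right": Z[:, 1].astype(int),
            "height": Z[:, 2],
        })


def _harvest_params(model, checkpoint: str) -> dict:
    if checkpoint == "final":
        return getattr(model, "final_params_", None) or model.params_
    if checkpoint == "best":
        return model.params_
    raise ValueError("checkpoint must be 'final' or 'best'")


def harvest_sites(model, X: np.ndarray, batch_size: int = 128,
                  checkpoint: str = "final") -> dict[int, list[str]]:
    """Collect the maximally activating l-mer per (sequence, kernel).

    For each kernel the subsequence at the argmax of the pre-pooling ReLU
    activation is taken iff that maximum is strictly greater than zero
    (leftmost position on ties).  Returns ``{kernel_id: [site, ...]}``.

    ``checkpoint`` selects which parameters to scan with: the
    final-epoch state (default; kernels keep sharpening after the
    best-validation epoch) or the best-validation checkpoint.
    """
    X = np.asarray(X)
    cfg = model.config_
    params = _harvest_params(model, checkpoint)
    l, h = cfg.kernel_len, cfg.n_kernels
    sites: dict[int, list[str]] = {k: [] for k in range(h)}
    for i0 in range(0, len(X), batch_size):
        batch = X[i0:i0 + batch_size]
        A = network.pre_pool_activations(batch, params, cfg)  # (b, P, h)
        pos = A.argmax(axis=1)                                       # (b, h)
        val = A.max(axis=1)
        for b in range(len(batch)):
            seq = one_hot_decode(batch[b])
            for k in range(h):
                if val[b, k] > 0:
                    p = int(pos[b, k])
                    sites[k].append(seq[p:p + l])
    return sites


def build_ppm(sites: list[str], kernel_id: int = 0, pseudocount: float = 0.0,
              min_sites: int = DEFAULT_MIN_SITES) -> Motif | None:
    """Column-wise base frequencies of equal-length sites, with optional
    additive pseudocount; rows renormalized to sum to 1.

    Returns None for an empty site list; motifs with fewer than
    ``min_sites`` sites are flagged ``low_support``.  Ambiguous bases (N)
    contribute to no column but still renormalize away.
    """
    if not sites:
        return None
    l = len(sites[0])
    if any(len(s) != l for s in sites):
        raise ValueError("all sites must have equal length")
    counts = np.zeros((l, 4), dtype=float)
    for s in sites:
        for i, base in enumerate(s.upper()):
            j = ALPHABET.find(base)
            if j >= 0:
                counts[i, j] += 1
    counts += pseudocount
    totals = counts.sum(axis=1, keepdims=True)
    if (totals == 0).any():
        raise ValueError("position with no countable bases and no pseudocount")
    return Motif(kernel_id=kernel_id, ppm=counts / totals, n_sites=len(sites),
                 low_support=len(sites) < min_sites)


def harvest_motifs(model, X: np.ndarray, pseudocount: float = 0.0,
                   min_sites: int = DEFAULT_MIN_SITES,
                   checkpoint: str = "final") -> list[Motif]:
    """End-to-end: harvest sites on X and build one Motif per active kernel."""
    out = []
    for k, sites in harvest_sites(model, X, checkpoint=checkpoint).items():
        m = build_ppm(sites, kernel_id=k, pseudocount=pseudocount,
                      min_sites=min_sites)
        if m is not None:
            out.append(m)
    return out


# ---------------------------------------------------------------------------
# MEME minimal motif format


def write_meme(motifs: list[Motif], path: str | Path,
               background: tuple[float, float, float, float] = (0.25,) * 4
               ) -> None:
    """Write motifs in MEME minimal format (letter-probability matrices).

    ``background`` is in A,C,G,T order, as are the matrix columns
    (converted from the internal A,G,C,T layout).
    """
    lines = [
        "MEME version 4", "",
        "ALPHABET= ACGT", "",
        "strands: + -", "",
        "Background letter frequencies",
        "A {:.5f} C {:.5f} G {:.5f} T {:.5f}".format(*background), "",
    ]
    for m in motifs:
        lines.append(f"MOTIF kernel_{m.kernel_id}")
        lines.append(
            f"letter-probability matrix: alength= 4 w= {m.length} "
            f"nsites= {m.n_sites} E= 0")
        for row in m.ppm[:, _AGCT_TO_ACGT]:
            lines.append(" ".join(f"{v:.6f}" for v in row))
        lines.append("")
    Path(path).write_text("\n".join(lines))


def read_meme(path: str | Path) -> list[Motif]:
    """Parse a MEME minimal motif file back into Motif objects."""
    motifs: list[Motif] = []
    rows: list[list[float]] = []
    name, nsites = None, 1

    def flush():
        nonlocal rows, name
        if name is not None and rows:
            acgt = np.asarray(rows)
            ppm = acgt[:, _AGCT_TO_ACGT]  # back to internal A,G,C,T
            kid = int(name.rsplit("_", 1)[-1]) if "_" in name else len(motifs)
            motifs.append(Motif(kernel_id=kid, ppm=ppm, n_sites=nsites))
        rows, name = [], None

    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line.startswith("MOTIF"):
            flush()
            name = line.split()[1]
        elif line.startswith("letter-probability matrix"):
            parts = line.split()
            if "nsites=" in parts:
                nsites = int(parts[parts.index("nsites=") + 1])
        elif name is not None and line and line[0] in "0123456789.":
            rows.append([float(v) for v in line.split()])
    flush()
    return motifs


# ---------------------------------------------------------------------------
# edit-distance deduplication


def consensus_edit_distance(c1: str, c2: str) -> int:
    """Levenshtein distance (unit insert/delete/substitute) by DP."""
    if not c1 or not c2:
        raise ValueError("consensus strings must be non-empty")
    prev = np.arange(len(c2) + 1)
    for i, a in enumerate(c1, start=1):
        cur = np.empty(len(c2) + 1, dtype=int)
        cur[0] = i
        for j, b in enumerate(c2, start=1):
            cur[j] = min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (a != b))
        prev = cur
    return int(prev[-1])


def cluster_motifs(motifs: list[Motif],
                   thresholds: tuple[int, ...] = DEFAULT_THRESHOLDS
                   ) -> MotifClustering:
    """Deduplicate motifs by complete-linkage clustering of consensus
    edit distances.

    For each threshold d, clusters are the groups obtained by cutting the
    dendrogram at height <= d (so two motifs share a cluster at d=0 only
    when their consensi are identical); ``distinct_count[d]`` is the
    number of clusters, non-increasing in d.
    """
    if not motifs:
        raise ValueError("need at least one motif")
    n = len(motifs)
    cons = [m.consensus for m in motifs]
    if n == 1:
        return MotifClustering(
            motifs=motifs, linkage_matrix=None,
            assignments={d: np.array([1]) for d in thresholds},
            distinct_count={d: 1 for d in thresholds})
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = consensus_edit_distance(cons[i], cons[j])
    Z = linkage(squareform(D), method="complete")
    assignments, distinct = {}, {}
    for d in thresholds:
        labels = fcluster(Z, t=d, criterion="distance")
        assignments[d] = labels
        distinct[d] = int(labels.max())
    return MotifClustering(motifs=motifs, linkage_matrix=Z,
                           assignments=assignments, distinct_count=distinct)


def contains_approximately(haystack: str, needle: str,
                           max_mismatch: int = 1) -> bool:
    """True iff ``needle`` occurs in ``haystack`` as an ungapped substring
    with at most ``max_mismatch`` mismatching positions."""
    n, m = len(haystack), len(needle)
    if m > n:
        return False
    for off in range(n - m + 1):
        mism = sum(a != b for a, b in zip(haystack[off:off + m], needle))
        if mism <= max_mismatch:
            return True
    return False
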