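"""Dataset construction from genome FASTA + ChIP-seq peak intervals.

The labeling recipe follows the multi-task ChIP-seq convention used by the
DeepSea family of models: the genome is tiled into non-overlapping 200 bp
bins; a bin is positive for a task iff strictly more than half of the bin is
covered by that task's peaks; each labeled bin is then extended by 400 bp of
flanking reference sequence on each side to form a 1,000 bp model input.
Coordinates are 0-based half-open (BED convention) throughout.

One-hot encoding uses column order A, G, C, T; ambiguous bases (N) encode to
all-zero rows.  Under this column order the reverse complement of a one-hot
matrix is simply the matrix reversed along both axes.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: column order of one-hot matrices
ALPHABET = "AGCT"
_BASE_TO_COL = {"A": 0, "G": 1, "C": 2, "T": 3}
_COL_TO_BASE = np.array(list(ALPHABET))

DEFAULT_BIN_SIZE = 200
DEFAULT_FLANK = 400


@dataclass(frozen=True)
class GenomicBin:
    """A genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(f"invalid interval {self.chrom}:{self.start}-{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start


def tile_genome(
    chrom_lengths: Mapping[str, int], bin_size: int = DEFAULT_BIN_SIZE
) -> list[GenomicBin]:
    """Tile each chromosome with non-overlapping ``bin_size`` bins from 0.

    A trailing partial bin (chromosome length not divisible by ``bin_size``)
    is discarded.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    if not chrom_lengths:
        raise ValueError("empty chromosome map")
    bins: list[GenomicBin] = []
    for chrom, length in chrom_lengths.items():
        for start in range(0, int(length) - bin_size + 1, bin_size):
            bins.append(GenomicBin(chrom, start, start + bin_size))
    return bins


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping/abutting half-open intervals into a sorted union."""
    ivs = sorted((int(s), int(e)) for s, e in intervals)
    merged: list[tuple[int, int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def _overlap_with_union(bin_: GenomicBin, merged: Sequence[tuple[int, int]]) -> int:
    total = 0
    for s, e in merged:
        if e <= bin_.start:
            continue
        if s >= bin_.end:
            break
        total += min(e, bin_.end) - max(s, bin_.start)
    return total


def label_bins(
    bins: Sequence[GenomicBin],
    peaks_per_task: Mapping[str, Mapping[str, Sequence[tuple[int, int]]]],
    task_names: Sequence[str] | None = None,
    union: bool = True,
) -> tuple[np.ndarray, list[str]]:
    """Label bins against per-task peak sets.

    Parameters
    ----------
    bins
        Bins to label.
    peaks_per_task
        ``{task: {chrom: [(start, end), ...]}}`` in 0-based half-open
        coordinates.
    task_names
        Task roster; defaults to the keys of ``peaks_per_task``.  A task
        with no peaks yields an all-zero column (with a warning).
    union
        If True (default), overlap is computed against the merged union of a
        task's peaks; if False, against the single best-overlapping peak.

    Returns
    -------
    labels : (n_bins, n_tasks) uint8 array
        ``labels[i, j] = 1`` iff strictly more than half of bin *i* is
        covered by task *j*'s peaks.
    tasks : list of task names defining column order.
    """
    tasks = list(task_names) if task_names is not None else list(peaks_per_task)
    labels = np.zeros((len(bins), len(tasks)), dtype=np.uint8)
    for j, task in enumerate(tasks):
        by_chrom = peaks_per_task.get(task)
        if not by_chrom:
            warnings.warn(f"task {task!r} has no peaks; all-zero labels", stacklevel=2)
            continue
        merged = {c: merge_intervals(ivs) for c, ivs in by_chrom.items()}
        raw = {c: sorted(map(tuple, ivs)) for c, ivs in by_chrom.items()}
        for i, b in enumerate(bins):
            if union:
                ov = _overlap_with_union(b, merged.get(b.chrom, ()))
            else:
                ov = max(
                    (
                        min(e, b.end) - max(s, b.start)
                        for s, e in raw.get(b.chrom, ())
                        if min(e, b.end) > max(s, b.start)
                    ),
                    default=0,
                )
            if ov * 2 > b.length:  # strictly more than half
                labels[i, j] = 1
    return labels, tasks


def extend_bin(
    bin_: GenomicBin, flank: int, chrom_length: int
) -> GenomicBin | None:
    """Attach ``flank`` bp of reference on each side of a bin.

    Returns None when the extension would leave chromosome bounds; such
    bins are dropped from the dataset (the caller records this in
    provenance).
    """
    if flank < 0:
        raise ValueError("flank must be non-negative")
    start, end = bin_.start - flank, bin_.end + flank
    if start < 0 or end > chrom_length:
        return None
    return GenomicBin(bin_.chrom, start, end)


def one_hot_encode(seq: str, dtype=np.float32) -> np.ndarray:
    """Encode a DNA string as an S x 4 one-hot matrix (columns A, G, C, T).

    Case-insensitive; N encodes to an all-zero row; any other character
    raises a ValueError naming the offending position.
    """
    s = seq.upper()
    out = np.zeros((len(s), 4), dtype=dtype)
    for i, base in enumerate(s):
        if base == "N":
            continue
        col = _BASE_TO_COL.get(base)
        if col is None:
            raise ValueError(f"invalid base {base!r} at position {i}")
        out[i, col] = 1
    return out


def one_hot_decode(x: np.ndarray) -> str:
    """Inverse of :func:`one_hot_encode`; all-zero rows decode to 'N'."""
    x = np.asarray(x)
    bases = _COL_TO_BASE[np.argmax(x, axis=1)]
    bases[x.sum(axis=1) == 0] = "N"
    return "".join(bases)


def reverse_complement(x: np.ndarray) -> np.ndarray:
    """Reverse complement of one-hot matrices (last two axes).

    Under column order A,G,C,T, complementing swaps columns 1<->4 and
    2<->3, i.e. reverses the column axis; the position axis is reversed as
    well.  Works on a single S x 4 matrix or a batch (n, S, 4).
    """
    x = np.asarray(x)
    return np.ascontiguousarray(x[..., ::-1, ::-1])


def reverse_complement_str(seq: str) -> str:
    comp = str.maketrans("ACGTNacgtn", "TGCANtgcan")
    return seq.translate(comp)[::-1]


@dataclass
class SequenceDataset:
    """Model-ready dataset: one-hot sequences, multi-task labels, split tags.

    Attributes
    ----------
    X : (n, S, 4) array
        One-hot encoded sequences, column order A,G,C,T.
    y : (n, T) uint8 array
        Binary labels, one column per task.
    task_names : list of str
    split : (n,) array of {"train","valid","test"}
    provenance : list of str
        Per-record origin ("chrom:start-end", "synthetic:<id>", or
        "rc:<forward provenance>").
    chrom : (n,) array of str
        Chromosome (or pseudo-chromosome for synthetic records).
    """

    X: np.ndarray
    y: np.ndarray
    task_names: list[str]
    split: np.ndarray
    provenance: list[str] = field(default_factory=list)
    chrom: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len(self.X) != len(self.y):
            raise ValueError("sequences and labels must have equal length")
        if self.y.ndim != 2 or self.y.shape[1] != len(self.task_names):
            raise ValueError("label width must match task roster")
        self.split = np.asarray(self.split, dtype=object)
        if not set(self.split) <= {"train", "valid", "test"}:
            raise ValueError("split tags must be train/valid/test")
        if not self.provenance:
            self.provenance = [f"record:{i}" for i in range(len(self.X))]

    def __len__(self) -> int:
        return len(self.X)

    def subset(self, split: str) -> "SequenceDataset":
        idx = np.flatnonzero(self.split == split)
        return SequenceDataset(
            X=self.X[idx],
            y=self.y[idx],
            task_names=self.task_names,
            split=self.split[idx],
            provenance=[self.provenance[i] for i in idx],
            chrom=None if self.chrom is None else self.chrom[idx],
        )

    def save(self, outdir: str | Path) -> None:
        """Write the dataset directory: dense matrices + JSON manifest."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        np.save(out / "sequences.npy", np.asarray(self.X, dtype=np.uint8))
        np.save(out / "labels.npy", np.asarray(self.y, dtype=np.uint8))
        records = pd.DataFrame(
            {
                "split": list(self.split),
                "provenance": self.provenance,
                "chrom": list(self.chrom) if self.chrom is not None else "",
            }
        )
        records.to_csv(out / "records.tsv", sep="\t", index=False)
        manifest = {
            "n_records": len(self),
            "seq_length": int(self.X.shape[1]),
            "task_names": self.task_names,
            "encoding_order": ALPHABET,
            "coordinates": "0-based half-open",
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def load(cls, indir: str | Path) -> "SequenceDataset":
        ind = Path(indir)
        manifest = json.loads((ind / "manifest.json").read_text())
        records = pd.read_csv(ind / "records.tsv", sep="\t", keep_default_na=False)
        chrom = records["chrom"].to_numpy(dtype=object)
        return cls(
            X=np.load(ind / "sequences.npy").astype(np.float32),
            y=np.load(ind / "labels.npy"),
            task_names=list(manifest["task_names"]),
            split=records["split"].to_numpy(dtype=object),
            provenance=list(records["provenance"]),
            chrom=None if (chrom == "").all() else chrom,
        )


def augment_reverse_complement(ds: SequenceDataset) -> SequenceDataset:
    """Append the reverse complement of every record (labels copied verbatim).

    The augmented record inherits the forward record's split tag, so a
    partner always lands in the same split; dataset size doubles.
    """
    return SequenceDataset(
        X=np.concatenate([ds.X, reverse_complement(ds.X)]),
        y=np.concatenate([ds.y, ds.y]),
        task_names=ds.task_names,
        split=np.concatenate([ds.split, ds.split]),
        provenance=ds.provenance + [f"rc:{p}" for p in ds.provenance],
        chrom=None if ds.chrom is None else np.concatenate([ds.chrom, ds.chrom]),
    )


def split_by_chromosome(
    chroms: Sequence[str],
    valid_chroms: Sequence[str],
    test_chroms: Sequence[str],
) -> np.ndarray:
    """Assign split tags by chromosome (held-out validation/test chromosomes).

    Chromosomes not listed go to the training split.  Overlapping valid and
    test rosters are an error.
    """
    valid, test = set(valid_chroms), set(test_chroms)
    if valid & test:
        raise ValueError(f"chromosomes in both valid and test: {sorted(valid & test)}")
    tags = np.empty(len(chroms), dtype=object)
    for i, c in enumerate(chroms):
        tags[i] = "valid" if c in valid else "test" if c in test else "train"
    return tags


def split_summary(split: Sequence[str]) -> pd.DataFrame:
    """Per-split record counts and percentages (2 decimals), plus a total row."""
    split = np.asarray(split, dtype=object)
    total = len(split)
    rows = []
    for name in ("train", "valid", "test"):
        n = int((split == name).sum())
        rows.append({"split": name, "n_samples": n, "ratio_pct": round(100.0 * n / total, 2)})
    rows.append({"split": "total", "n_samples": total, "ratio_pct": 100.0})
    return pd.DataFrame(rows)


def build_dataset(
    fasta_path: str | Path,
    peaks_per_task: Mapping[str, Mapping[str, Sequence[tuple[int, int]]]],
    bin_size: int = DEFAULT_BIN_SIZE,
    flank: int = DEFAULT_FLANK,
    valid_chroms: Sequence[str] = ("chr7",),
    test_chroms: Sequence[str] = ("chr8", "chr9"),
    add_reverse_complement: bool = True,
    keep_all_negative: bool = False,
) -> SequenceDataset:
    """Full dataset-construction pipeline from FASTA + peak intervals.

    Tiles the genome, labels bins by the strict majority-overlap rule,
    extends each labeled bin by ``flank`` bp on each side (bins running off
    the chromosome are dropped), one-hot encodes the extended sequences,
    splits by chromosome, and optionally appends reverse complements.

    By default only bins positive for at least one task are kept
    (``keep_all_negative=False``); set it to True to keep the full tiling.
    """
    from pyfaidx import Fasta

    fasta = Fasta(str(fasta_path), sequence_always_upper=True)
    chrom_lengths = {name: len(fasta[name]) for name in fasta.keys()}
    bins = tile_genome(chrom_lengths, bin_size)
    labels, tasks = label_bins(bins, peaks_per_task)
    if not keep_all_negative:
        keep = labels.any(axis=1)
        bins = [b for b, k in zip(bins, keep) if k]
        labels = labels[keep]

    X_rows, y_rows, prov, chroms = [], [], [], []
    for b, lab in zip(bins, labels):
        ext = extend_bin(b, flank, chrom_lengths[b.chrom])
        if ext is None:  # extension leaves the chromosome: drop
            continue
        seq = str(fasta[ext.chrom][ext.start : ext.end])
        X_rows.append(one_hot_encode(seq))
        y_rows.append(lab)
        prov.append(f"{b.chrom}:{b.start}-{b.end}")
        chroms.append(b.chrom)
    if not X_rows:
        raise ValueError("no usable bins after labeling/extension")
    ds = SequenceDataset(
        X=np.stack(X_rows),
        y=np.stack(y_rows),
        task_names=tasks,
        split=split_by_chromosome(chroms, valid_chroms, test_chroms),
        provenance=prov,
        chrom=np.array(chroms, dtype=object),
    )
    if add_reverse_complement:
        ds = augment_reverse_complement(ds)
    return ds


def read_bed_intervals(path: str | Path) -> dict[str, list[tuple[int, int]]]:
    """Read a BED3+/narrowPeak file into ``{chrom: [(start, end), ...]}``.

    Columns beyond the first three are ignored.
    """
    df = pd.read_csv(
        path, sep="\t", header=None, usecols=[0, 1, 2], comment="#",
        names=["chrom", "start", "end"],
    )
    out: dict[str, list[tuple[int, int]]] = {}
    for chrom, sub in df.groupby("chrom", sort=False):
        out[str(chrom)] = list(zip(sub["start"].astype(int), sub["end"].astype(int)))
    return out
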