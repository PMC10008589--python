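"""Quantify A-to-I editing from amplicon reads and cytometry-style fold change.

Inosine is read as guanosine by polymerases, so ADAR editing appears as A->G
substitutions in sequencing: a per-position pileup over amplicon reads gives
the editing fraction G/(A+G) at every reference adenosine.  The denominator
is A+G rather than total depth so that sequencing errors to C/T do not
deflate the estimate; positions with A+G below ``min_depth`` are reported as
missing.

The fluorescence readout is the output fold change: the ratio of geometric
means of reporter intensity with and without trigger, with a percentile
bootstrap 95% CI.  Cells can be binned by transfection-marker intensity at
half-log10 intervals before computing per-bin statistics, and closed-loop
vs open-loop topologies are compared with log10 ratios of fold change and
basal (OFF-state) level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO

from .seq_core import Transcript, normalize_seq

__all__ = [
    "EditingTable",
    "FoldChangeResult",
    "bin_by_marker",
    "fold_change",
    "logo_matrix",
    "pileup",
    "topology_ratios",
]

BASES = "ACGTN"
_BASE_CODE = np.full(256, 4, dtype=np.int8)  # anything odd counts as N
for _i, _b in enumerate(BASES):
    _BASE_CODE[ord(_b)] = _i
    _BASE_CODE[ord(_b.lower())] = _i
_BASE_CODE[ord("U")] = _BASE_CODE[ord("u")] = 3  # U -> T


@dataclass
class EditingTable:
    """Per-position base counts and A->G editing fractions for one reference."""

    reference_id: str
    reference_seq: str
    counts: np.ndarray  # positions x 5 (A, C, G, T, N)
    min_depth: int = 100
    n_reads: int = 0
    n_discarded: int = 0

    @property
    def depth(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def editing_fraction(self) -> np.ndarray:
        """G/(A+G) at reference-A positions; NaN elsewhere or below min_depth."""
        a = self.counts[:, 0].astype(float)
        g = self.counts[:, 2].astype(float)
        denom = a + g
        frac = np.full(len(self.reference_seq), np.nan)
        is_a = np.frombuffer(self.reference_seq.encode(), dtype=np.uint8) == ord("A")
        ok = is_a & (denom >= self.min_depth)
        frac[ok] = g[ok] / denom[ok]
        return frac

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, columns=list(BASES))
        df.insert(0, "ref_base", list(self.reference_seq))
        df.insert(0, "position", np.arange(1, len(self.reference_seq) + 1))
        df["depth"] = self.depth
        df["editing_fraction"] = self.editing_fraction
        return df


def _encode(seqs: Sequence[str]) -> np.ndarray:
    joined = "".join(seqs).encode()
    codes = _BASE_CODE[np.frombuffer(joined, dtype=np.uint8)]
    return codes.reshape(len(seqs), -1)


def _resolve_reference(reference) -> tuple[str, str]:
    if isinstance(reference, Transcript):
        return reference.id, reference.seq
    if isinstance(reference, tuple):
        rid, seq = reference
        return rid, normalize_seq(seq)
    return "reference", normalize_seq(str(reference))


def _pileup_fastq_reads(
    seqs: list[str], ref_seq: str, counts: np.ndarray, max_mismatch_frac: float
) -> tuple[int, int]:
    """Ungapped minimum-mismatch placement of fixed-construct amplicon reads."""
    ref_codes = _BASE_CODE[np.frombuffer(ref_seq.encode(), dtype=np.uint8)]
    by_len: dict[int, list[str]] = {}
    for s in seqs:
        by_len.setdefault(len(s), []).append(s)
    used = discarded = 0
    for read_len, group in by_len.items():
        if read_len > len(ref_seq) or read_len == 0:
            discarded += len(group)
            continue
        codes = _encode(group)  # n x read_len
        n_offsets = len(ref_seq) - read_len + 1
        cost = np.empty((len(group), n_offsets), dtype=np.int32)
        for off in range(n_offsets):
            cost[:, off] = (codes != ref_codes[off : off + read_len]).sum(axis=1)
        best_off = cost.argmin(axis=1)
        best_cost = cost[np.arange(len(group)), best_off]
        ceiling = int(np.floor(max_mismatch_frac * read_len))
        keep = best_cost <= ceiling
        discarded += int((~keep).sum())
        used += int(keep.sum())
        for off in np.unique(best_off[keep]):
            sub = codes[keep & (best_off == off)]
            for j in range(read_len):
                counts[off + j] += np.bincount(sub[:, j], minlength=5)
    return used, discarded


def _pileup_sam(path: Path, ref_id: str, ref_seq: str, counts: np.ndarray) -> tuple[int, int]:
    used = discarded = 0
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        names = set(sam.references or ())
        if names and ref_id not in names:
            raise ValueError(
                f"reference {ref_id!r} not found in SAM header (has {sorted(names)})"
            )
        for rec in sam.fetch(until_eof=True):
            if rec.is_unmapped or rec.query_sequence is None:
                discarded += 1
                continue
            if names and rec.reference_name != ref_id:
                discarded += 1
                continue
            # SAM stores SEQ in reference orientation, so reverse-strand
            # records are already complemented.
            query = rec.query_sequence.upper()
            for qpos, rpos in rec.get_aligned_pairs(matches_only=True):
                if 0 <= rpos < len(ref_seq):
                    counts[rpos, _BASE_CODE[ord(query[qpos])]] += 1
            used += 1
    return used, discarded


def pileup(
    reads,
    reference,
    min_depth: int = 100,
    max_mismatch_frac: float = 0.2,
) -> EditingTable:
    """Per-position base counts and editing fractions from reads.

    ``reads`` may be a SAM path, a FASTQ path, or an iterable of read
    sequences (strings).  FASTQ / raw reads are placed by ungapped
    minimum-mismatch offset search against the reference (ties to the
    leftmost offset); reads whose best placement exceeds
    ``max_mismatch_frac`` of their length are discarded and counted in
    ``n_discarded``.  SAM alignments are used as given (indels allowed).
    """
    ref_id, ref_seq = _resolve_reference(reference)
    counts = np.zeros((len(ref_seq), 5), dtype=np.int64)

    if isinstance(reads, (str, Path)):
        path = Path(reads)
        if not path.exists():
            raise FileNotFoundError(path)
        if path.suffix.lower() == ".sam":
            used, discarded = _pileup_sam(path, ref_id, ref_seq, counts)
        else:
            seqs = [str(r.seq).upper().replace("U", "T") for r in SeqIO.parse(str(path), "fastq")]
            used, discarded = _pileup_fastq_reads(seqs, ref_seq, counts, max_mismatch_frac)
    else:
        seqs = [normalize_seq(s) for s in reads]
        used, discarded = _pileup_fastq_reads(seqs, ref_seq, counts, max_mismatch_frac)

    if used == 0:
        warnings.warn(f"no usable reads for {ref_id}; editing table is empty", UserWarning)
    return EditingTable(
        reference_id=ref_id,
        reference_seq=ref_seq,
        counts=counts,
        min_depth=min_depth,
        n_reads=used,
        n_discarded=discarded,
    )


def logo_matrix(table: EditingTable, window: tuple[int, int] | None = None) -> pd.DataFrame:
    """Per-position base frequency matrix (each position's frequencies sum to 1).

    Rows are 0-based reference positions within ``window`` (default: all),
    columns A/C/G/T/N.  Zero-depth positions come out as all-NaN rows
    (missing marker).  Suitable input for sequence-logo rendering or CSV
    export; an unedited sample is a point mass on the reference base at
    every position, while an edited sample splits the central A between A
    and G.
    """
    start, end = window if window is not None else (0, len(table.reference_seq))
    if not (0 <= start < end <= len(table.reference_seq)):
        raise ValueError(f"window [{start}, {end}) outside reference")
    sub = table.counts[start:end].astype(float)
    depth = sub.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(depth > 0, sub / depth, np.nan)
    return pd.DataFrame(
        freq, index=pd.Index(range(start, end), name="position"), columns=list(BASES)
    )


def bin_by_marker(
    intensities: Sequence[float] | np.ndarray | pd.Series,
    log10_bin_width: float = 0.5,
) -> tuple[pd.DataFrame, int]:
    """Assign cells to marker-intensity bins at (by default) half-log intervals.

    Bin edges are anchored at 10^0: bin ``k`` covers ``[10^(k*w), 10^((k+1)*w))``
    with ``w = log10_bin_width``.  Returns the assignment table (intensity,
    bin index, bin edges) and the count of excluded non-positive cells.
    """
    if log10_bin_width <= 0:
        raise ValueError("log10_bin_width must be positive")
    values = np.asarray(intensities, dtype=float)
    positive = values > 0
    n_excluded = int((~positive).sum())
    kept = values[positive]
    idx = np.floor(np.log10(kept) / log10_bin_width).astype(int)
    df = pd.DataFrame(
        {
            "intensity": kept,
            "bin": idx,
            "bin_lo": 10.0 ** (idx * log10_bin_width),
            "bin_hi": 10.0 ** ((idx + 1) * log10_bin_width),
        }
    )
    return df, n_excluded


@dataclass
class FoldChangeResult:
    geo_mean_on: float
    geo_mean_off: float
    fold_change: float
    ci95: tuple[float, float]
    n_on: int
    n_off: int


def _geomean(x: np.ndarray) -> float:
    return float(np.exp(np.mean(np.log(x))))


def fold_change(
    on_cells: Sequence[float] | np.ndarray,
    off_cells: Sequence[float] | np.ndarray,
    n_boot: int = 1000,
    seed: int = 0,
) -> FoldChangeResult:
    """Output fold change: ratio of geometric-mean reporter intensity ON/OFF.

    The 95% CI is a percentile bootstrap over cells (both arms resampled
    independently), seeded for reproducibility.  Intensities must be
    positive; floor or filter upstream (e.g. instrument baseline) before
    calling.
    """
    on = np.asarray(on_cells, dtype=float)
    off = np.asarray(off_cells, dtype=float)
    if on.size == 0 or off.size == 0:
        raise ValueError("both populations must be non-empty")
    if (on <= 0).any() or (off <= 0).any():
        raise ValueError(
            "non-positive intensities present; geometric means are undefined — "
            "floor or filter them upstream"
        )
    log_on, log_off = np.log(on), np.log(off)
    fc = float(np.exp(log_on.mean() - log_off.mean()))

    rng = np.random.default_rng(seed)
    boot_on = rng.integers(0, on.size, size=(n_boot, on.size))
    boot_off = rng.integers(0, off.size, size=(n_boot, off.size))
    samples = np.exp(log_on[boot_on].mean(axis=1) - log_off[boot_off].mean(axis=1))
    lo, hi = np.percentile(samples, [2.5, 97.5])
    return FoldChangeResult(
        geo_mean_on=_geomean(on),
        geo_mean_off=_geomean(off),
        fold_change=fc,
        ci95=(float(lo), float(hi)),
        n_on=int(on.size),
        n_off=int(off.size),
    )


def topology_ratios(cl: FoldChangeResult, ol: FoldChangeResult) -> dict[str, float | bool]:
    """Closed-loop vs open-loop comparison for a matched sensor variant.

    Returns ``log10_fold_change_ratio`` = log10(FC_CL / FC_OL) (positive
    means the sensor performs better with autocatalysis) and
    ``log10_basal_ratio`` = log10(OFF_CL / OFF_OL) (negative means reduced
    background activation in the closed loop).
    """
    if ol.fold_change == 0 or ol.geo_mean_off == 0:
        raise ValueError("open-loop denominators must be non-zero")
    fc_ratio = float(np.log10(cl.fold_change / ol.fold_change))
    basal_ratio = float(np.log10(cl.geo_mean_off / ol.geo_mean_off))
    return {
        "log10_fold_change_ratio": fc_ratio,
        "log10_basal_ratio": basal_ratio,
        "better_with_autocatalysis": fc_ratio > 0,
    }
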