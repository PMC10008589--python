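"""Synthetic-data generation: triggers, amplicon reads and cytometry tables.

Every pipeline stage is testable without downloads.  The generator emulates
the three experimental inputs of an ADAR-sensor study:

* a trigger transcript (random background, CCA motifs planted at exact
  start-codon-anchored positions and nowhere else),
* amplicon sequencing reads over a sensor region with per-position A->G
  editing probabilities (the ~30% exogenous-ADAR and ~3% endogenous-ADAR
  regimes are the defaults of interest) plus optional uniform base errors,
* per-cell fluorescence tables drawn from log-normal populations, matching
  the geometric-mean fold-change readout (defaults: n = 2000 cells per arm,
  the study's minimum cell count; planted fold change 9, the upper end of
  basic-sensor activation).

All outputs are fully determined by ``SimSpec.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .seq_core import Localization, Region, RegionKind, Transcript, write_fasta
from .sensor_designer import DEFAULT_LENGTH, DesignRejection, design_sensor
from .site_finder import scan_cca

__all__ = [
    "SimSpec",
    "make_snv_pair",
    "make_trigger",
    "simulate_cells",
    "simulate_reads",
    "write_trigger",
]


@dataclass
class SimSpec:
    """Parameters of the synthetic study; the seed fully determines outputs."""

    seed: int = 0
    # trigger
    trigger_length: int = 500
    utr5_length: int = 60
    cds_length: int = 300
    planted_cca_positions: tuple[int, ...] = (60,)  # start-codon-anchored, +1 = A of ATG
    localization: Localization = Localization.CYTOPLASMIC
    secreted: bool = False
    ensure_designable: bool = True  # reject backgrounds whose planted sites can't carry a sensor
    sensor_length: int = DEFAULT_LENGTH
    # reads
    read_depth: int = 5000
    editing_rates: dict[int, float] = field(default_factory=dict)  # 0-based ref offset -> P(A->G)
    error_rate: float = 0.0
    quality_char: str = "I"
    # cells
    n_cells: int = 2000
    mean_log_off: float = float(np.log(100.0))
    true_fold_change: float = 9.0
    sd_log: float = 1.0

    def __post_init__(self) -> None:
        for p in self.editing_rates.values():
            if not 0.0 <= p <= 1.0:
                raise ValueError("editing probabilities must be in [0, 1]")
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError("error_rate must be in [0, 1)")


_BASES = np.array(list("ACGT"))


def _random_seq(rng: np.random.Generator, n: int) -> list[str]:
    return list(rng.choice(_BASES, size=n))


def _scrub_cca(seq: list[str], rng: np.random.Generator, keep: set[int]) -> None:
    """Mutate the A of every CCA whose first C is not in ``keep``; iterate to a fixpoint."""
    changed = True
    while changed:
        changed = False
        s = "".join(seq)
        start = 0
        while True:
            hit = s.find("CCA", start)
            if hit == -1:
                break
            if hit not in keep:
                seq[hit + 2] = rng.choice(["C", "G", "T"])
                changed = True
            start = hit + 1


def make_trigger(spec: SimSpec) -> Transcript:
    """Build a trigger transcript with CCA exactly at the planted anchored positions.

    The background is rejection-sampled so that a CCA occurs at each planted
    start-codon-anchored position and nowhere else.  The layout is
    5'UTR / CDS / 3'UTR with an ATG start and TAA stop.  With
    ``ensure_designable`` (default) backgrounds whose planted sites would be
    rejected by the sensor designer (residual in-frame stop in the
    reverse-complement window) are resampled, so the trigger is usable
    end-to-end.
    """
    if spec.utr5_length + spec.cds_length > spec.trigger_length:
        raise ValueError("UTR5 + CDS exceed trigger length")
    if spec.cds_length % 3 != 0:
        raise ValueError("CDS length must be a multiple of 3")
    plants = sorted(spec.planted_cca_positions)
    for a, b in zip(plants, plants[1:]):
        if b - a < 4:
            raise ValueError("planted CCA positions must be >= 4 apart")
    cds_start = spec.utr5_length
    offsets = [cds_start + p - 1 for p in plants]
    for off in offsets:
        if not (0 <= off and off + 3 <= spec.trigger_length):
            raise ValueError(f"planted anchored position maps outside the transcript ({off})")

    rng = np.random.default_rng(spec.seed)
    keep = set(offsets)
    for _attempt in range(500):
        seq = _random_seq(rng, spec.trigger_length)
        # fixed landmarks: start codon and terminal CDS stop
        seq[cds_start : cds_start + 3] = list("ATG")
        cds_end = cds_start + spec.cds_length
        seq[cds_end - 3 : cds_end] = list("TAA")
        for off in offsets:
            seq[off : off + 3] = list("CCA")
        _scrub_cca(seq, rng, keep)
        s = "".join(seq)
        # scrubbing or planting may have disturbed landmarks; verify everything
        if s[cds_start : cds_start + 3] != "ATG" or s[cds_end - 3 : cds_end] != "TAA":
            continue
        found = []
        start = 0
        while (hit := s.find("CCA", start)) != -1:
            found.append(hit)
            start = hit + 1
        if found != offsets:
            continue
        transcript = Transcript(
            id=f"trigger_seed{spec.seed}",
            seq=s,
            regions=[
                Region(RegionKind.FIVE_PRIME_UTR, 0, cds_start),
                Region(RegionKind.CDS, cds_start, cds_end),
                Region(RegionKind.THREE_PRIME_UTR, cds_end, spec.trigger_length),
            ]
            if cds_end < spec.trigger_length
            else [
                Region(RegionKind.FIVE_PRIME_UTR, 0, cds_start),
                Region(RegionKind.CDS, cds_start, cds_end),
            ],
            localization=spec.localization,
            secreted=spec.secreted,
        )
        if spec.ensure_designable:
            sites = scan_cca(transcript)
            ok = True
            for site in sites:
                try:
                    result = design_sensor(transcript, site, spec.sensor_length)
                except Exception:
                    ok = False
                    break
                if isinstance(result, DesignRejection):
                    ok = False
                    break
            if not ok:
                continue
        return transcript
    raise RuntimeError(
        "could not realise the trigger spec in 500 attempts; too many planted "
        "sites for the length, or infeasible constraints"
    )


def write_trigger(transcript: Transcript, fasta_path: str | Path, regions_path: str | Path) -> None:
    """Write a trigger as FASTA plus the 3-column TSV region table (1-based inclusive)."""
    write_fasta([(transcript.id, transcript.seq)], fasta_path)
    with open(regions_path, "w") as fh:
        for r in transcript.regions:
            fh.write(f"{r.kind.value}\t{r.start + 1}\t{r.end}\n")


def make_snv_pair(spec: SimSpec, cds_position: int = 658) -> tuple[Transcript, str]:
    """A wild-type transcript plus a variant spec whose ALT creates a CCA.

    The local context at the (1-based CDS) variant position is forced to
    C-T-A in the wild type, so ``c.<pos>T>C`` creates the discriminating CCA
    in the mutant — the structure of a tumour-suppressor point-variant
    sensor (c.658T>C / codon 220).  Returns ``(wild_type, "c.<pos>T>C")``.
    """
    if spec.cds_length < cds_position + 2:
        raise ValueError("cds_length too short for the requested variant position")
    from .sensor_designer import design_snv_sensor

    variant = f"c.{cds_position}T>C"
    for seed_offset in range(0, 101 * 50, 101):  # deterministic retry ladder
        base = make_trigger(
            SimSpec(
                seed=spec.seed + seed_offset,
                trigger_length=spec.trigger_length,
                utr5_length=spec.utr5_length,
                cds_length=spec.cds_length,
                planted_cca_positions=(),
                localization=spec.localization,
                secreted=spec.secreted,
                ensure_designable=False,
            )
        )
        cds_start = base.cds_start
        assert cds_start is not None
        var_off = cds_start + cds_position - 1
        seq = list(base.seq)
        seq[var_off - 1 : var_off + 2] = list("CTA")
        rng = np.random.default_rng(spec.seed + seed_offset + 1)
        _scrub_cca(seq, rng, keep=set())  # WT carries no CCA, so the variant diff is clean
        s = "".join(seq)
        if s[var_off - 1 : var_off + 2] != "CTA":
            continue
        wt = Transcript(
            id=f"{base.id}_wt", seq=s, regions=list(base.regions),
            localization=base.localization, secreted=base.secreted,
        )
        # the designer also needs the mutant window stop-free; verify so
        # callers get a deterministic, usable pair
        attempt = design_snv_sensor(wt, variant, spec.sensor_length)
        if not isinstance(attempt, DesignRejection):
            return wt, variant
    raise RuntimeError("could not realise a designable SNV pair in 50 attempts")


# ---------------------------------------------------------------------------
# reads


def simulate_reads(
    reference: Transcript | str,
    spec: SimSpec,
    out_fastq: str | Path | None = None,
) -> list[str]:
    """Simulate ``spec.read_depth`` full-length amplicon reads of ``reference``.

    Each reference-A position listed in ``spec.editing_rates`` is converted
    to G independently per read with its planted probability; every position
    then suffers a uniform substitution error at ``spec.error_rate`` (default
    0, keeping recovery oracles exact).  Returns read sequences; optionally
    writes FASTQ with constant quality.
    """
    ref_seq = reference.seq if isinstance(reference, Transcript) else str(reference).upper()
    for off in spec.editing_rates:
        if not (0 <= off < len(ref_seq)):
            raise ValueError(f"editing rate at offset {off} outside reference")
        if ref_seq[off] != "A":
            raise ValueError(f"editing rate planted at non-A reference position {off}")

    rng = np.random.default_rng(spec.seed)
    n, L = spec.read_depth, len(ref_seq)
    codes = np.frombuffer(ref_seq.encode(), dtype=np.uint8)
    reads = np.tile(codes, (n, 1))
    for off, p in sorted(spec.editing_rates.items()):
        mask = rng.random(n) < p
        reads[mask, off] = ord("G")
    if spec.error_rate > 0:
        err = rng.random((n, L)) < spec.error_rate
        # replace with a uniformly random *different* base
        shift = rng.integers(1, 4, size=err.sum())
        base_idx = np.searchsorted(np.frombuffer(b"ACGT", dtype=np.uint8), reads[err])
        reads[err] = np.frombuffer(b"ACGT", dtype=np.uint8)[(base_idx + shift) % 4]

    seqs = [row.tobytes().decode() for row in reads]
    if out_fastq is not None:
        qual = spec.quality_char * L
        with open(out_fastq, "w") as fh:
            for i, s in enumerate(seqs):
                fh.write(f"@read{i}\n{s}\n+\n{qual}\n")
    return seqs


# ---------------------------------------------------------------------------
# cells


def simulate_cells(spec: SimSpec, out_csv: str | Path | None = None) -> pd.DataFrame:
    """Per-cell marker and reporter intensities for ON and OFF populations.

    Reporter intensities are log-normal with
    ``mean_log_on = mean_log_off + ln(true_fold_change)``, so the planted
    geometric-mean fold change is exactly ``spec.true_fold_change``; the
    transfection marker is log-normal and trigger-independent.  Columns:
    ``population`` ('on'/'off'), ``marker``, ``reporter``.
    """
    if spec.sd_log <= 0:
        raise ValueError("sd_log must be positive")
    if spec.n_cells < 1:
        raise ValueError("need at least one cell per arm")
    rng = np.random.default_rng(spec.seed)
    mean_on = spec.mean_log_off + float(np.log(spec.true_fold_change))
    frames = []
    for pop, mean_log in (("off", spec.mean_log_off), ("on", mean_on)):
        frames.append(
            pd.DataFrame(
                {
                    "population": pop,
                    "marker": rng.lognormal(mean=np.log(500.0), sigma=spec.sd_log, size=spec.n_cells),
                    "reporter": rng.lognormal(mean=mean_log, sigma=spec.sd_log, size=spec.n_cells),
                }
            )
        )
    df = pd.concat(frames, ignore_index=True)
    if out_csv is not None:
        df.to_csv(out_csv, index=False)
    return df
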