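"""Enumerate, name, classify and rank editable CCA sites on a target transcript.

An ADAR sensor places its editable A (the middle of an in-frame UAG) opposite
the central C of a ``CCA`` trinucleotide on the target, which gives the
adenosine the favourable A:C mismatch and 5'-U neighbour.  Candidate sites are
therefore exactly the CCA occurrences on the trigger.  Sites are named
``CCA<n>`` where ``n`` is the 1-based, start-codon-anchored position of the
first C of the motif (plain 1-based transcript position when no CDS is
annotated); the anchoring convention is configurable via :class:`SiteNaming`.

Ranking encodes the empirical targeting rules: ribosome-free sequence is a
better substrate, so coding sequence of secreted (ER-targeted, ribosome-
stalled) products ranks first, then 3'UTR, then 5'UTR, with translated CDS
last; nuclear transcripts are excluded outright (cytoplasmic editing only —
sensors against nuclear RNAs show no activation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum

from .seq_core import Localization, RegionKind, Transcript

__all__ = [
    "Context",
    "EditSite",
    "NuclearTargetWarning",
    "RankPolicy",
    "SiteNaming",
    "classify_context",
    "rank_sites",
    "scan_cca",
]

MOTIF = "CCA"


class Context(str, Enum):
    CDS_TRANSLATED = "cds_translated"
    CDS_SECRETED = "cds_secreted"
    THREE_PRIME_UTR = "three_prime_utr"
    FIVE_PRIME_UTR = "five_prime_utr"
    NONCODING = "noncoding"


class SiteNaming(str, Enum):
    """Which base of the CCA motif the site number refers to."""

    FIRST_C = "first_c"
    CENTRAL_C = "central_c"
    A = "a"


_NAMING_OFFSET = {SiteNaming.FIRST_C: 0, SiteNaming.CENTRAL_C: 1, SiteNaming.A: 2}


class NuclearTargetWarning(UserWarning):
    """Advisory emitted when ranking sites on a nuclear-localized transcript."""


@dataclass
class EditSite:
    """A CCA occurrence on a transcript, the anchor of a candidate sensor."""

    transcript_id: str
    motif_start: int  # 0-based offset of the first C
    name: str
    anchored_position: int  # 1-based, start-codon-anchored when CDS annotated
    context: Context | None = None
    rank_score: int | None = None

    @property
    def central_c(self) -> int:
        """0-based offset of the central C (the base the editable A opposes)."""
        return self.motif_start + 1


def scan_cca(transcript: Transcript, naming: SiteNaming = SiteNaming.FIRST_C) -> list[EditSite]:
    """Report every CCA occurrence in ascending position, overlaps included.

    ``CCACCA`` yields sites at offsets 0 and 3; ``CCCA`` yields one site at
    offset 1.  Windows are filtered later by the designer; this scan is
    exhaustive by design.
    """
    if len(transcript) < 3:
        raise ValueError(f"{transcript.id}: transcript shorter than the CCA motif")
    sites: list[EditSite] = []
    start = 0
    seq = transcript.seq
    while True:
        hit = seq.find(MOTIF, start)
        if hit == -1:
            break
        anchored = transcript.anchored_position(hit + _NAMING_OFFSET[naming])
        sites.append(
            EditSite(
                transcript_id=transcript.id,
                motif_start=hit,
                name=f"CCA{anchored}",
                anchored_position=anchored,
            )
        )
        start = hit + 1  # overlapping occurrences count
    return sites


def classify_context(site: EditSite, transcript: Transcript) -> Context:
    """Assign the regulatory context of the region containing the motif start.

    CDS on a secreted-product transcript classifies as ``cds_secreted``; a
    site outside every annotated region is ``noncoding`` with a warning.
    """
    region = transcript.region_at(site.motif_start)
    if region is None:
        if transcript.regions:
            warnings.warn(
                f"{site.name} on {transcript.id} falls outside all annotated regions; "
                "classifying as noncoding",
                UserWarning,
                stacklevel=2,
            )
        site.context = Context.NONCODING
        return site.context
    if region.kind is RegionKind.CDS:
        site.context = Context.CDS_SECRETED if transcript.secreted else Context.CDS_TRANSLATED
    elif region.kind is RegionKind.THREE_PRIME_UTR:
        site.context = Context.THREE_PRIME_UTR
    else:
        site.context = Context.FIVE_PRIME_UTR
    return site.context


@dataclass
class RankPolicy:
    """Context priorities for site ranking (lower is better).

    The default order follows the measured activation trend: secreted-product
    CDS above 3'UTR, both far above translated CDS.
    """

    priority: dict[Context, int] = field(
        default_factory=lambda: {
            Context.CDS_SECRETED: 0,
            Context.THREE_PRIME_UTR: 1,
            Context.FIVE_PRIME_UTR: 2,
            Context.CDS_TRANSLATED: 3,
            Context.NONCODING: 4,
        }
    )
    exclude_nuclear: bool = True


def rank_sites(
    sites: list[EditSite],
    transcript: Transcript,
    policy: RankPolicy | None = None,
) -> list[EditSite]:
    """Order classified sites by context priority, ties broken by position.

    Nuclear-localized transcripts return an empty ranking with a
    :class:`NuclearTargetWarning` advisory: sensors against nuclear RNAs
    (e.g. MALAT1) showed no output activation, so such targets are excluded
    rather than down-weighted.  The ranking is a total order and invariant
    to the input ordering of ``sites``.
    """
    policy = policy or RankPolicy()
    if policy.exclude_nuclear and transcript.localization is Localization.NUCLEAR:
        warnings.warn(
            f"{transcript.id} is nuclear-localized: ADAR sensor editing is cytoplasmic "
            "and nuclear targets do not activate; no sites ranked",
            NuclearTargetWarning,
            stacklevel=2,
        )
        return []
    for site in sites:
        if site.context is None:
            classify_context(site, transcript)
    ranked = sorted(
        sites, key=lambda s: (policy.priority.get(s.context, len(policy.priority)), s.motif_start)
    )
    for i, site in enumerate(ranked, start=1):
        site.rank_score = i
    return ranked
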