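"""Consensus-site and TSR motif scanning for tryptophan C-mannosylation.

C-mannosylation attaches a single alpha-mannose through a C-C bond to the
indole C2 atom of a tryptophan, typically inside the consensus sequence
WxxW or WxxC (``x`` = any residue).  Thrombospondin type 1 repeats (TSRs)
carry the extended conserved motif W-x-x-W-x-x-W-x-x-C; all three of its
tryptophans can be C-mannosylated (W1/W2 by DPY19L1, W3 by DPY19L3).

Positions are reported 1-based throughout, following residue-numbering
convention.  Overlapping matches are all reported; a tryptophan may serve
both as the first W of one window and as the "+3" partner of another.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Union

#: The 20 standard amino-acid one-letter codes.  Scanning windows containing
#: anything else (X/U/B/Z placeholders, gaps, stop characters) never match.
STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")

WXXW = "WxxW"
WXXC = "WxxC"


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with its accession."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein id must be non-empty")
        if not self.sequence:
            raise ValueError(f"protein {self.id!r}: sequence must be non-empty")
        object.__setattr__(self, "sequence", self.sequence.upper())


@dataclass(frozen=True)
class ConsensusSite:
    """A C-mannosylation consensus tryptophan.

    ``position`` is the 1-based index of the modifiable W; ``kind`` says
    whether the +3 partner is W or C; ``context`` is the 4-residue window
    starting at the site.
    """

    position: int
    kind: str
    context: str

    def __post_init__(self) -> None:
        if self.kind not in (WXXW, WXXC):
            raise ValueError(f"kind must be {WXXW!r} or {WXXC!r}, got {self.kind!r}")
        if len(self.context) != 4 or self.context[0] != "W":
            raise ValueError(f"invalid context {self.context!r}")
        expected = "W" if self.kind == WXXW else "C"
        if self.context[3] != expected:
            raise ValueError(f"context {self.context!r} inconsistent with kind {self.kind}")


@dataclass(frozen=True)
class TsrMotifHit:
    """A WxxWxxWxxC match: three mannosylatable tryptophans spaced +3."""

    start: int
    mannosylatable_tryptophans: tuple[int, int, int]

    def __post_init__(self) -> None:
        w1, w2, w3 = self.mannosylatable_tryptophans
        if not (w1 == self.start and w2 == w1 + 3 and w3 == w2 + 3):
            raise ValueError("tryptophans must start at the hit and be spaced +3")


@dataclass(frozen=True)
class GroupMotifAnnotation:
    """Motif call for a protein group (any-member semantics).

    ``has_consensus`` is True if any member with an available sequence has at
    least one consensus site, False if all resolvable members are motif-free,
    and None when no member sequence could be resolved (the group is then
    excluded from the motif-positive set rather than counted as motif-free).
    """

    group_id: str
    member_ids: tuple[str, ...]
    has_consensus: Optional[bool]
    sites_per_member: Mapping[str, tuple[ConsensusSite, ...]] = field(default_factory=dict)
    unresolved: tuple[str, ...] = ()


def _window_standard(window: str) -> bool:
    return all(ch in STANDARD_AA for ch in window)


def scan_consensus_sites(sequence: str) -> list[ConsensusSite]:
    """Return every WxxW/WxxC consensus site in ``sequence``, sorted by position.

    A site is a 1-based position ``i`` with W at ``i`` and W or C at ``i + 3``.
    Overlapping sites are all kept.  Windows containing non-standard letters
    never match (conservative handling of X/U/B/Z, gaps and stops).

    Raises
    ------
    ValueError
        If the sequence is empty.
    """
    if not sequence:
        raise ValueError("cannot scan an empty sequence")
    seq = sequence.upper()
    sites: list[ConsensusSite] = []
    for i in range(len(seq) - 3):
        window = seq[i : i + 4]
        if window[0] != "W" or not _window_standard(window):
            continue
        if window[3] == "W":
            sites.append(ConsensusSite(i + 1, WXXW, window))
        elif window[3] == "C":
            sites.append(ConsensusSite(i + 1, WXXC, window))
    return sites


def find_tsr_motifs(sequence: str) -> list[TsrMotifHit]:
    """Find WxxWxxWxxC motifs (the TSR tryptophan ladder) in ``sequence``.

    Each hit spans 10 consecutive residues with W at offsets 0, 3, 6 and C at
    offset 9; the three W positions are exactly the consensus sites W1/W2
    (WxxW kind) and W3 (WxxC kind) that :func:`scan_consensus_sites` reports.
    """
    if not sequence:
        raise ValueError("cannot scan an empty sequence")
    seq = sequence.upper()
    hits: list[TsrMotifHit] = []
    for i in range(len(seq) - 9):
        window = seq[i : i + 10]
        if not _window_standard(window):
            continue
        if window[0] == "W" and window[3] == "W" and window[6] == "W" and window[9] == "C":
            hits.append(TsrMotifHit(i + 1, (i + 1, i + 4, i + 7)))
    return hits


def annotate_groups(
    groups: Iterable[tuple[str, Sequence[str]]],
    db: Union[Mapping[str, ProteinRecord], Iterable[ProteinRecord]],
    require_resolved: frozenset[str] = frozenset(),
) -> list[GroupMotifAnnotation]:
    """Annotate protein groups with consensus-site presence (any-member rule).

    Parameters
    ----------
    groups
        Iterable of ``(group_id, member_accessions)`` pairs, typically parsed
        from the semicolon-separated ID column of a protein-group table.
    db
        Protein records, as a mapping accession → record or an iterable.
    require_resolved
        Group ids that must resolve at least one member sequence; a group in
        this set with zero resolvable members raises instead of warning.

    Members absent from ``db`` are recorded as unresolved — absence of a
    sequence is never treated as evidence of a motif-free protein.
    """
    if not isinstance(db, Mapping):
        db = {rec.id: rec for rec in db}
    annotations: list[GroupMotifAnnotation] = []
    for group_id, members in groups:
        members = tuple(members)
        sites: dict[str, tuple[ConsensusSite, ...]] = {}
        unresolved: list[str] = []
        for acc in members:
            rec = db.get(acc)
            if rec is None:
                unresolved.append(acc)
            else:
                sites[acc] = tuple(scan_consensus_sites(rec.sequence))
        if not sites:
            if group_id in require_resolved:
                raise ValueError(
                    f"group {group_id!r} is flagged for candidate selection but "
                    f"none of its members {members} resolve to a sequence"
                )
            has: Optional[bool] = None
        else:
            has = any(s for s in sites.values())
        if unresolved:
            warnings.warn(
                f"group {group_id!r}: unresolved accessions {unresolved}",
                stacklevel=2,
            )
        annotations.append(
            GroupMotifAnnotation(group_id, members, has, sites, tuple(unresolved))
        )
    return annotations


def motif_positive_groups(annotations: Iterable[GroupMotifAnnotation]) -> set[str]:
    """Group ids called motif-positive (``has_consensus is True``)."""
    return {a.group_id for a in annotations if a.has_consensus is True}
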