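"""Candidate selection and Pfam domain enrichment.

Candidates are significantly changed protein groups that carry at least one
C-mannosylation consensus site (per knockout, plus the union).  Domain
enrichment asks, for each Pfam domain, whether the candidate set contains
more domain-bearing proteins than expected from the filtered extracellular
background, via a one-sided Fisher exact test (the hypergeometric tail).
The background can also be rescreened directly for a domain of interest
(e.g. TSP_1, the thrombospondin type 1 repeat) to surface proteins the
significance screen missed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence, Set

import numpy as np
from scipy import stats

from .secretome import DifferentialResult


@dataclass(frozen=True)
class EnrichmentResult:
    """One domain's 2x2 enrichment test against the background.

    k: foreground groups with the domain; n: foreground size;
    K: background groups with the domain; N: background size.
    """

    domain: str
    k: int
    n: int
    K: int
    N: int
    odds_ratio: float
    p: float

    def __post_init__(self) -> None:
        if not (0 <= self.k <= min(self.n, self.K) and self.n <= self.N and self.K <= self.N):
            raise ValueError(
                f"inconsistent table for {self.domain}: "
                f"k={self.k} n={self.n} K={self.K} N={self.N}"
            )


@dataclass(frozen=True)
class CandidateSelection:
    """Significant ∩ motif-positive groups, per KO and unioned."""

    per_ko: Mapping[str, frozenset[str]]
    union: frozenset[str]


def select_candidates(
    diff_results: Mapping[str, DifferentialResult],
    motif_positive: Set[str],
) -> CandidateSelection:
    """Intersect each contrast's significant groups with the motif-positive set.

    ``motif_positive`` holds group ids whose group-level motif call is True
    (any-member semantics); groups with unknown motif status must not be in
    this set and are therefore excluded.
    """
    per_ko = {
        ko: frozenset(res.significant_ids & motif_positive)
        for ko, res in diff_results.items()
    }
    union: frozenset[str] = frozenset().union(*per_ko.values()) if per_ko else frozenset()
    return CandidateSelection(per_ko, union)


def _groups_with_domain(
    groups: Iterable[str],
    members: Mapping[str, Sequence[str]],
    domains: Mapping[str, Set[str]],
    domain: str,
) -> set[str]:
    """Any-member domain call, mirroring the motif annotation semantics."""
    hit = set()
    for gid in groups:
        for acc in members.get(gid, (gid,)):
            if domain in domains.get(acc, frozenset()):
                hit.add(gid)
                break
    return hit


def fisher_domain_enrichment(
    foreground: Set[str],
    background: Set[str],
    domains: Mapping[str, Set[str]],
    members: Optional[Mapping[str, Sequence[str]]] = None,
    alpha: float = 0.05,
    two_sided: bool = False,
) -> list[EnrichmentResult]:
    """Fisher exact enrichment of each domain in foreground vs background.

    ``domains`` maps accessions to Pfam domain-name sets; ``members`` maps
    group ids to member accessions (defaults to the group id itself being the
    accession).  The one-sided (greater) p is the hypergeometric tail
    P[X >= k] of the 2x2 table (k, n−k, K−k, N−n−K+k).  Domains absent from
    the foreground (k = 0) are skipped.  Results sorted by p.
    """
    if not foreground <= background:
        raise ValueError("foreground must be a subset of the background")
    members = members or {}
    all_domains: set[str] = set()
    for gid in background:
        for acc in members.get(gid, (gid,)):
            all_domains |= set(domains.get(acc, frozenset()))
    n, N = len(foreground), len(background)
    results: list[EnrichmentResult] = []
    for dom in sorted(all_domains):
        bg_hit = _groups_with_domain(background, members, domains, dom)
        fg_hit = bg_hit & foreground
        k, K = len(fg_hit), len(bg_hit)
        if k == 0:
            continue
        if two_sided:
            _, p = stats.fisher_exact(
                [[k, n - k], [K - k, N - n - (K - k)]], alternative="two-sided"
            )
        else:
            # one-sided enrichment: hypergeometric survival P[X >= k]
            p = float(stats.hypergeom.sf(k - 1, N, K, n))
        num = k * (N - n - (K - k))
        den = (n - k) * (K - k)
        odds = num / den if den > 0 else np.inf
        results.append(EnrichmentResult(dom, k, n, K, N, float(odds), float(p)))
    results.sort(key=lambda r: (r.p, r.domain))
    return results


def rescreen_domain(
    background: Set[str],
    domains: Mapping[str, Set[str]],
    domain: str = "TSP_1",
    members: Optional[Mapping[str, Sequence[str]]] = None,
) -> list[str]:
    """All background groups with >= 1 member annotated with ``domain``.

    A domain name that occurs nowhere in the annotation yields an empty list
    with a warning rather than an error.
    """
    members = members or {}
    known = set()
    for doms in domains.values():
        known |= set(doms)
    if domain not in known:
        warnings.warn(f"domain {domain!r} not present in the annotation snapshot")
        return []
    return sorted(_groups_with_domain(background, members, domains, domain))
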