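"""Reciprocal-best-hit orthology and species-presence classification.

Every protein in a K-organism database is assigned the exact set of
organisms in which it has itself or a reciprocal best hit (RBH): its
species-presence category, one of the 2^K - 1 non-empty organism subsets.
"Best hit" means minimal E-value, with ties broken by higher bit score and
then lexicographically smaller subject id. A protein's category always
contains its own organism; a protein with no RBH partner is
lineage-specific (singleton category).

Coverage curation mirrors post-hoc manual curation of pair categories:
within the scoped categories, a protein is rejected when a supporting best
hit spans less than a minimum fraction of the protein's own sequence — the
signature of a domain-only or partial match rather than full-length
orthology.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io import Proteome

#: key: (query protein id, target organism) -> best AlignmentHit
BestHitMap = dict[tuple[str, str], "object"]


@dataclass
class CategoryAssignment:
    """One protein's species-presence category with its supporting RBH
    partners (at most one per partner organism)."""

    protein_id: str
    organism: str
    category: frozenset[str]
    partners: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.organism not in self.category:
            raise ValueError(
                f"category of {self.protein_id!r} must contain its own organism {self.organism!r}"
            )
        extra = set(self.partners) - (self.category - {self.organism})
        if extra:
            raise ValueError(f"partners listed for organisms outside the category: {sorted(extra)}")


def category_label(category: Iterable[str]) -> str:
    return "+".join(sorted(category))


def enumerate_categories(organisms: Sequence[str]) -> list[frozenset[str]]:
    """All 2^K - 1 non-empty organism subsets, ordered by size then
    lexicographically by sorted member names."""
    if len(organisms) == 0:
        raise ValueError("need at least one organism")
    if len(set(organisms)) != len(organisms):
        raise ValueError("duplicate organism names")
    cats: list[frozenset[str]] = []
    names = sorted(organisms)
    for size in range(1, len(names) + 1):
        for combo in combinations(names, size):
            cats.append(frozenset(combo))
    return cats


def best_hits(hits: Iterable, e_cutoff: float, org_of: Mapping[str, str]) -> BestHitMap:
    """Reduce a hit table to the single best hit per (query, target organism).

    Hits with E-value above the cutoff are discarded. Ranking: minimal
    E-value, then maximal bit score, then lexicographically smallest
    subject id.
    """
    if e_cutoff <= 0:
        raise ValueError("e_cutoff must be positive")
    best: BestHitMap = {}
    for lineno, h in enumerate(hits, start=1):
        try:
            query, subject, evalue, bits = h.query, h.subject, h.evalue, h.bits
        except AttributeError as exc:
            raise ValueError(f"malformed hit row {lineno}: {exc}") from exc
        if subject not in org_of:
            raise ValueError(f"hit row {lineno}: subject {subject!r} has no known organism")
        if evalue > e_cutoff:
            continue
        key = (query, org_of[subject])
        cur = best.get(key)
        if cur is None or (evalue, -bits, subject) < (cur.evalue, -cur.bits, cur.subject):
            best[key] = h
    return best


def reciprocal_best_hits(best: BestHitMap, org_of: Mapping[str, str]) -> set[frozenset[str]]:
    """Unordered cross-organism pairs {p, q} where each is the other's best
    hit in its organism."""
    pairs: set[frozenset[str]] = set()
    for (p, target_org), hit in best.items():
        q = hit.subject
        back = best.get((q, org_of[p]))
        if back is not None and back.subject == p:
            pairs.add(frozenset((p, q)))
    return pairs


def classify_proteins(
    pairs: set[frozenset[str]],
    org_of: Mapping[str, str],
    best: BestHitMap | None = None,
) -> list[CategoryAssignment]:
    """Assign every protein in the database its species-presence category:
    its own organism plus the organisms of all its RBH partners.

    ``org_of`` defines the protein universe; every protein receives exactly
    one assignment (singleton category when it has no partner).
    """
    partner_map: dict[str, dict[str, str]] = {p: {} for p in org_of}
    for pair in pairs:
        p, q = sorted(pair)
        for a, b in ((p, q), (q, p)):
            if a not in org_of or b not in org_of:
                raise ValueError(f"RBH pair names protein {a if a not in org_of else b!r} absent from the proteomes")
            partner_map[a][org_of[b]] = b
    assignments = []
    for pid in org_of:
        partners = partner_map[pid]
        category = frozenset({org_of[pid], *partners})
        assignments.append(
            CategoryAssignment(protein_id=pid, organism=org_of[pid], category=category, partners=partners)
        )
    return assignments


def _resolve_scope(
    scope: str | Iterable[frozenset[str]],
    organisms: Sequence[str],
) -> set[frozenset[str]]:
    all_cats = set(enumerate_categories(organisms))
    if scope == "pairs":
        return {c for c in all_cats if len(c) == 2}
    if scope == "all":
        return all_cats
    requested = {frozenset(c) for c in scope}
    unknown = requested - all_cats
    if unknown:
        raise ValueError(f"scope names unknown categories: {sorted(category_label(c) for c in unknown)}")
    return requested


def curate_coverage(
    assignments: Sequence[CategoryAssignment],
    best: BestHitMap,
    min_cov: float = 0.20,
    scope: str | Iterable[frozenset[str]] = "pairs",
    organisms: Sequence[str] | None = None,
) -> tuple[list[CategoryAssignment], pd.DataFrame]:
    """Reject scoped proteins whose supporting best hits cover too little of
    their own sequence.

    For each assignment whose category is in scope (default: the
    two-organism pair categories), every supporting best hit (the protein as
    query) is examined; if the aligned span covers less than ``min_cov`` of
    the protein's own length, the assignment is moved to the rejection list
    with the offending partner and coverage recorded. All other assignments
    pass through unchanged.
    """
    if not 0 <= min_cov <= 1:
        raise ValueError("min_cov must be in [0, 1]")
    if organisms is None:
        organisms = sorted({a.organism for a in assignments})
    scoped = _resolve_scope(scope, organisms)
    kept: list[CategoryAssignment] = []
    rejected_rows: list[dict] = []
    for a in assignments:
        reason = None
        if a.category in scoped:
            for org, partner in sorted(a.partners.items()):
                hit = best.get((a.protein_id, org))
                if hit is None:
                    continue
                cov = hit.query_coverage
                if cov < min_cov:
                    reason = {
                        "protein_id": a.protein_id,
                        "organism": a.organism,
                        "category": category_label(a.category),
                        "partner": partner,
                        "coverage": round(cov, 4),
                        "reason": f"query coverage {cov:.2%} below {min_cov:.0%}",
                    }
                    break
        if reason is None:
            kept.append(a)
        else:
            rejected_rows.append(reason)
    rejections = pd.DataFrame(
        rejected_rows,
        columns=["protein_id", "organism", "category", "partner", "coverage", "reason"],
    )
    return kept, rejections


def category_counts(
    assignments: Sequence[CategoryAssignment],
    organisms: Sequence[str],
    complete: bool = True,
) -> pd.DataFrame:
    """Category x organism protein-count table (one row per category).

    With ``complete=True`` all 2^K - 1 categories appear, zeros included;
    the grand total always equals the number of assignments.
    """
    cats = enumerate_categories(organisms)
    labels = [category_label(c) for c in cats]
    counts = pd.DataFrame(0, index=labels, columns=list(organisms), dtype=int)
    for a in assignments:
        counts.loc[category_label(a.category), a.organism] += 1
    if not complete:
        counts = counts.loc[counts.sum(axis=1) > 0]
    counts.index.name = "category"
    return counts


def pair_specific_proteins(
    assignments: Sequence[CategoryAssignment],
    category: Iterable[str],
    organisms: Sequence[str] | None = None,
) -> list[str]:
    """Proteins whose category equals the requested organism set exactly."""
    cat = frozenset(category)
    if organisms is not None and cat not in set(enumerate_categories(organisms)):
        raise ValueError(f"unknown category {category_label(cat)!r}")
    if not cat:
        raise ValueError("category must be non-empty")
    return sorted(a.protein_id for a in assignments if a.category == cat)


def assignments_table(assignments: Sequence[CategoryAssignment]) -> pd.DataFrame:
    rows = [
        {
            "protein_id": a.protein_id,
            "organism": a.organism,
            "category": category_label(a.category),
            "partners": ";".join(f"{o}:{p}" for o, p in sorted(a.partners.items())),
        }
        for a in assignments
    ]
    return pd.DataFrame(rows, columns=["protein_id", "organism", "category", "partners"])
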