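"""Hypergeometric term enrichment, process classes, and overlap reporting.

A sample of proteins (e.g. one species-presence category) is tested term
by term against a background universe with the hypergeometric upper tail.
A term is retained when its p-value clears the cutoff (default 1e-4, no
multiple-testing correction — an optional Benjamini-Hochberg flag exists)
and it annotates at least ``min_proteins`` sample proteins (default 3;
a strict greater-than reading is available). Retained terms then induce
per-protein process classes (trafficking / cytokinesis / metabolism, with
"other" and "unknown" fallbacks, plus manual overrides standing in for
curated reassignments), and the overlap report counts single-class,
bifunctional and trifunctional proteins with an inclusion-exclusion
consistency check.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy.stats import false_discovery_control, hypergeom

PROCESS_CLASSES = ("trafficking", "cytokinesis", "metabolism")
FALLBACK_CLASSES = ("other", "unknown")


@dataclass
class AnnotationSet:
    """Protein -> term annotations plus the term table (name, class)."""

    protein_terms: dict[str, frozenset[str]]
    term_names: dict[str, str] = field(default_factory=dict)
    term_classes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        known = set(self.term_classes)
        if known:
            referenced = set().union(*self.protein_terms.values()) if self.protein_terms else set()
            dangling = referenced - known
            if dangling:
                raise ValueError(f"proteins reference terms missing from the term table: {sorted(dangling)[:5]}")
        bad = set(self.term_classes.values()) - set(PROCESS_CLASSES) - {"other"}
        if bad:
            raise ValueError(f"unknown process classes in term table: {sorted(bad)}")

    @classmethod
    def from_tables(cls, annotations: pd.DataFrame, terms: pd.DataFrame | None = None) -> "AnnotationSet":
        """Build from a (protein_id, term_id) table and an optional term
        table with columns (term_id, name, process_class)."""
        protein_terms: dict[str, set[str]] = {}
        for pid, tid in zip(annotations["protein_id"], annotations["term_id"]):
            protein_terms.setdefault(pid, set()).add(tid)
        term_names: dict[str, str] = {}
        term_classes: dict[str, str] = {}
        if terms is not None:
            for _, row in terms.iterrows():
                term_names[row["term_id"]] = row.get("name", row["term_id"])
                term_classes[row["term_id"]] = row.get("process_class", "other")
        return cls(
            protein_terms={p: frozenset(t) for p, t in protein_terms.items()},
            term_names=term_names,
            term_classes=term_classes,
        )

    def terms_of(self, protein_id: str) -> frozenset[str]:
        return self.protein_terms.get(protein_id, frozenset())


def hypergeometric_tail(k: int, M: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N population, M carriers, n draws)."""
    if not 0 <= M <= N:
        raise ValueError(f"need 0 <= M <= N, got M={M}, N={N}")
    if not 0 <= n <= N:
        raise ValueError(f"need 0 <= n <= N, got n={n}, N={N}")
    if not 0 <= k <= min(n, M):
        raise ValueError(f"need 0 <= k <= min(n, M)={min(n, M)}, got k={k}")
    return float(hypergeom.sf(k - 1, N, M, n))


@dataclass
class EnrichmentResult:
    term_id: str
    k: int
    n: int
    M: int
    N: int
    p: float
    retained: bool
    name: str = ""
    process_class: str = ""
    p_adjusted: float | None = None


def enrich(
    sample: Iterable[str],
    annotations: AnnotationSet,
    background: Iterable[str],
    p_cutoff: float = 1e-4,
    min_proteins: int = 3,
    strict_min: bool = False,
    bh_correction: bool = False,
) -> list[EnrichmentResult]:
    """Per-term hypergeometric enrichment of ``sample`` against ``background``.

    One result per term annotating at least one sample protein, sorted by
    (p, term id). Retention: p below ``p_cutoff`` and k >= ``min_proteins``
    (k > with ``strict_min``). With ``bh_correction`` the retention p is
    the Benjamini-Hochberg adjusted value instead of the raw one.
    """
    sample = sorted(set(sample))
    background_set = set(background)
    if not background_set:
        raise ValueError("background must be non-empty")
    stray = set(sample) - background_set
    if stray:
        raise ValueError(f"sample proteins missing from background: {sorted(stray)[:5]}")
    if not sample:
        return []
    N = len(background_set)
    n = len(sample)
    sample_carriers: dict[str, int] = {}
    bg_carriers: dict[str, int] = {}
    for pid in background_set:
        for term in annotations.terms_of(pid):
            bg_carriers[term] = bg_carriers.get(term, 0) + 1
    for pid in sample:
        for term in annotations.terms_of(pid):
            sample_carriers[term] = sample_carriers.get(term, 0) + 1

    results = []
    for term in sorted(sample_carriers):
        k = sample_carriers[term]
        M = bg_carriers[term]
        p = hypergeometric_tail(k, M, n, N)
        results.append(EnrichmentResult(
            term_id=term, k=k, n=n, M=M, N=N, p=p, retained=False,
            name=annotations.term_names.get(term, term),
            process_class=annotations.term_classes.get(term, ""),
        ))
    if bh_correction and results:
        adjusted = false_discovery_control([r.p for r in results], method="bh")
        for r, q in zip(results, adjusted):
            r.p_adjusted = float(q)
    for r in results:
        effective_p = r.p_adjusted if bh_correction else r.p
        count_ok = r.k > min_proteins if strict_min else r.k >= min_proteins
        r.retained = (effective_p < p_cutoff) and count_ok
    results.sort(key=lambda r: (r.p, r.term_id))
    return results


def enrichment_table(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    rows = [
        {
            "term_id": r.term_id, "name": r.name, "process_class": r.process_class,
            "k": r.k, "n": r.n, "M": r.M, "N": r.N,
            "p": r.p, "p_adjusted": r.p_adjusted, "retained": r.retained,
        }
        for r in results
    ]
    return pd.DataFrame(rows, columns=[
        "term_id", "name", "process_class", "k", "n", "M", "N", "p", "p_adjusted", "retained",
    ])


def assign_process_classes(
    sample: Iterable[str],
    annotations: AnnotationSet,
    retained_terms: Iterable[str],
    overrides: Mapping[str, Iterable[str]] | None = None,
) -> dict[str, frozenset[str]]:
    """Process-class set per sample protein.

    A protein's classes are the union of process classes of retained terms
    annotating it, intersected with the three core classes. Overrides
    (modelling manual curation) replace the computed set. Proteins with no
    core class fall back to {"other"} when annotated at all, else
    {"unknown"}.
    """
    sample = list(dict.fromkeys(sample))
    retained = set(retained_terms)
    overrides = dict(overrides or {})
    stray = set(overrides) - set(sample)
    if stray:
        raise ValueError(f"overrides name proteins outside the sample: {sorted(stray)[:5]}")
    out: dict[str, frozenset[str]] = {}
    core = set(PROCESS_CLASSES)
    for pid in sample:
        if pid in overrides:
            classes = frozenset(overrides[pid])
            bad = classes - core - set(FALLBACK_CLASSES)
            if bad:
                raise ValueError(f"override for {pid!r} names unknown classes: {sorted(bad)}")
            out[pid] = classes
            continue
        terms = annotations.terms_of(pid)
        classes = {
            annotations.term_classes.get(t, "other")
            for t in terms if t in retained
        } & core
        if classes:
            out[pid] = frozenset(classes)
        elif terms:
            out[pid] = frozenset({"other"})
        else:
            out[pid] = frozenset({"unknown"})
    return out


@dataclass
class OverlapReport:
    """Process-class bookkeeping over one protein sample.

    ``class_totals`` are inclusive (a bifunctional protein increments each
    of its classes); exclusive pair counts exclude the trifunctional
    proteins, so multi_total = sum(pair_exclusive) + triple.
    """

    sample_size: int
    class_totals: dict[str, int]
    single_exclusive: dict[str, int]
    pair_inclusive: dict[tuple[str, str], int]
    pair_exclusive: dict[tuple[str, str], int]
    triple: int
    multi_total: int
    other: int
    unknown: int

    def to_frame(self) -> pd.DataFrame:
        rows = [{"item": "sample_size", "count": self.sample_size}]
        rows += [{"item": f"total_{c}", "count": v} for c, v in self.class_totals.items()]
        rows += [{"item": f"only_{c}", "count": v} for c, v in self.single_exclusive.items()]
        rows += [{"item": f"pair_{a}+{b}", "count": v} for (a, b), v in self.pair_exclusive.items()]
        rows += [
            {"item": "triple", "count": self.triple},
            {"item": "multi_class_total", "count": self.multi_total},
            {"item": "other_function", "count": self.other},
            {"item": "unknown_function", "count": self.unknown},
        ]
        return pd.DataFrame(rows, columns=["item", "count"])


def overlap_report(class_assignments: Mapping[str, Iterable[str]]) -> OverlapReport:
    """Count single-, bi- and trifunctional proteins over the three core
    process classes, asserting inclusion-exclusion consistency."""
    core = set(PROCESS_CLASSES)
    class_totals = {c: 0 for c in PROCESS_CLASSES}
    single_exclusive = {c: 0 for c in PROCESS_CLASSES}
    pair_order = list(combinations(PROCESS_CLASSES, 2))
    pair_inclusive = {p: 0 for p in pair_order}
    pair_exclusive = {p: 0 for p in pair_order}
    triple = other = unknown = 0
    multi_total = 0
    for pid, classes in class_assignments.items():
        cs = frozenset(classes)
        bad = cs - core - set(FALLBACK_CLASSES)
        if bad:
            raise ValueError(f"protein {pid!r} carries unknown classes: {sorted(bad)}")
        cc = cs & core
        for c in cc:
            class_totals[c] += 1
        if len(cc) == 0:
            if "unknown" in cs:
                unknown += 1
            else:
                other += 1
        elif len(cc) == 1:
            single_exclusive[next(iter(cc))] += 1
        else:
            multi_total += 1
            for pair in pair_order:
                if set(pair) <= cc:
                    pair_inclusive[pair] += 1
                    if len(cc) == 2:
                        pair_exclusive[pair] += 1
            if len(cc) == 3:
                triple += 1
    assert multi_total == sum(pair_exclusive.values()) + triple, \
        "inclusion-exclusion identity violated"
    assert sum(single_exclusive.values()) + multi_total + other + unknown == len(class_assignments), \
        "class partition does not cover the sample"
    return OverlapReport(
        sample_size=len(class_assignments),
        class_totals=class_totals,
        single_exclusive=single_exclusive,
        pair_inclusive=pair_inclusive,
        pair_exclusive=pair_exclusive,
        triple=triple,
        multi_total=multi_total,
        other=other,
        unknown=unknown,
    )
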