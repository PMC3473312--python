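"""Family x organism presence/absence profiling.

The presence matrix counts, per protein family (or subfamily/type label),
how many proteins each organism carries. Profiles are compared between
organisms with the Jaccard distance on binarized presence, and a
discrimination test reports the families that separate one organism group
from another (the basis for taxon-bipartition claims such as
Opisthokonta-versus-Plantae splits).
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .phylo import DistanceMatrix


def build_presence_matrix(
    assignments: pd.DataFrame,
    organisms: Sequence[str] | None = None,
    family_col: str = "family",
) -> pd.DataFrame:
    """Count matrix cell(family, organism) = proteins of that organism in
    that family.

    ``assignments`` needs columns (organism, protein_id, family). Declared
    organisms with no assignment appear as all-zero columns — absence is
    signal. Duplicate protein ids are an error.
    """
    required = {"organism", "protein_id", family_col}
    missing = required - set(assignments.columns)
    if missing:
        raise ValueError(f"assignment table lacks columns: {sorted(missing)}")
    if assignments["protein_id"].duplicated().any():
        dupes = assignments.loc[assignments["protein_id"].duplicated(), "protein_id"]
        raise ValueError(f"duplicate protein ids in assignment table: {sorted(set(dupes))[:5]}")
    matrix = (
        assignments.groupby([family_col, "organism"], sort=True)
        .size()
        .unstack(fill_value=0)
    )
    if organisms is not None:
        matrix = matrix.reindex(columns=list(organisms), fill_value=0)
    matrix.index.name = "family"
    matrix.columns.name = "organism"
    return matrix.astype(int)


def profile_distance_matrix(matrix: pd.DataFrame, metric: str = "jaccard") -> DistanceMatrix:
    """Jaccard distances between organisms' binarized presence profiles.

    d(o1, o2) = 1 - |P1 n P2| / |P1 u P2| on presence sets; two all-absent
    organisms are at distance 0 by convention (scipy's handling of empty
    unions).
    """
    if metric != "jaccard":
        raise ValueError(f"unsupported metric {metric!r}")
    if matrix.shape[1] < 2:
        raise ValueError("need at least 2 organisms")
    presence = (matrix.to_numpy() > 0).T  # organisms x families
    with np.errstate(invalid="ignore"):
        d = squareform(pdist(presence, metric="jaccard"))
    d = np.nan_to_num(d, nan=0.0)  # all-absent vs all-absent
    return DistanceMatrix(list(matrix.columns), d)


def discriminating_families(
    matrix: pd.DataFrame,
    group_a: Iterable[str],
    group_b: Iterable[str],
    mode: str = "all",
) -> pd.DataFrame:
    """Families whose presence separates organism group A from group B.

    Mode "all": present in every organism of one group and absent from
    every organism of the other (direction labelled "A" or "B" for the
    group carrying the family). Mode "majority": presence fraction >= 0.5
    in one group and <= 0.5 in the other, fractions reported.
    """
    group_a, group_b = list(group_a), list(group_b)
    if not group_a or not group_b:
        raise ValueError("groups must be non-empty")
    overlap = set(group_a) & set(group_b)
    if overlap:
        raise ValueError(f"groups overlap: {sorted(overlap)}")
    unknown = (set(group_a) | set(group_b)) - set(matrix.columns)
    if unknown:
        raise ValueError(f"groups name unknown organisms: {sorted(unknown)}")
    if mode not in ("all", "majority"):
        raise ValueError(f"unknown mode {mode!r}")

    present = matrix > 0
    frac_a = present[group_a].mean(axis=1)
    frac_b = present[group_b].mean(axis=1)
    if mode == "all":
        dir_a = (frac_a == 1.0) & (frac_b == 0.0)
        dir_b = (frac_b == 1.0) & (frac_a == 0.0)
    else:
        dir_a = (frac_a >= 0.5) & (frac_b <= 0.5) & (frac_a > frac_b)
        dir_b = (frac_b >= 0.5) & (frac_a <= 0.5) & (frac_b > frac_a)
    rows = []
    for fam in matrix.index:
        if dir_a[fam] or dir_b[fam]:
            rows.append({
                "family": fam,
                "direction": "A" if dir_a[fam] else "B",
                "fraction_group_a": float(frac_a[fam]),
                "fraction_group_b": float(frac_b[fam]),
            })
    return pd.DataFrame(rows, columns=["family", "direction", "fraction_group_a", "fraction_group_b"])
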