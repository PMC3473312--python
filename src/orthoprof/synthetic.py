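"""Synthetic proteomes with planted ortholog families, paralogs and decoys.

The generator emulates a K-organism protein database in which every
downstream inference has a known answer: ortholog families are planted with
controlled species-presence patterns, within-family divergence follows a
single-hit per-site substitution model with an exact closed form, decoys are
unrelated random sequences, and term annotations carry planted enriched
process classes. One root seed drives per-family child streams in a fixed
order, so adding decoys or annotations never perturbs family sequences.

Substitution model: over a branch of length ``d`` (expected substitutions
per site) each site is independently replaced with probability 1 - e^(-d);
the replacement is uniform over the other 19 residues. There are no indels;
partial homology (for coverage filtering) is instead planted via
"fragment" proteins whose homologous region is a stated fraction of their
own length, the remainder being unrelated sequence.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .io import AMINO_ACIDS, Proteome, write_fasta, write_tsv

# BLOSUM62 background residue frequencies (Robinson & Robinson marginals as
# used by BLAST), indexed in AMINO_ACIDS order.
BLOSUM62_FREQS = {
    "A": 0.074, "C": 0.025, "D": 0.054, "E": 0.054, "F": 0.047,
    "G": 0.074, "H": 0.026, "I": 0.068, "K": 0.058, "L": 0.099,
    "M": 0.025, "N": 0.045, "P": 0.039, "Q": 0.034, "R": 0.052,
    "S": 0.057, "T": 0.051, "V": 0.073, "W": 0.013, "Y": 0.032,
}

UNIFORM_FREQS = np.full(20, 1.0 / 20.0)

_AA_ARRAY = np.frombuffer(AMINO_ACIDS.encode(), dtype=np.uint8)
_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}


def residue_frequencies(kind: str = "uniform") -> np.ndarray:
    """Background amino-acid frequency vector in alphabet order."""
    if kind == "uniform":
        return UNIFORM_FREQS.copy()
    if kind == "blosum62":
        return np.array([BLOSUM62_FREQS[a] for a in AMINO_ACIDS])
    raise ValueError(f"unknown frequency set {kind!r}; use 'uniform' or 'blosum62'")


def sample_ancestral_sequence(length: int, freqs: np.ndarray, rng: np.random.Generator) -> str:
    """Draw ``length`` residues i.i.d. from the frequency vector ``freqs``."""
    if length < 1:
        raise ValueError(f"sequence length must be >= 1, got {length}")
    freqs = np.asarray(freqs, dtype=float)
    if freqs.shape != (20,):
        raise ValueError("freqs must be a 20-element vector in alphabet order")
    if abs(freqs.sum() - 1.0) > 1e-9:
        raise ValueError(f"freqs must sum to 1 within 1e-9 (sum={freqs.sum()!r})")
    idx = rng.choice(20, size=length, p=freqs)
    return _AA_ARRAY[idx].tobytes().decode()


def evolve_sequence(seq: str, d: float, rng: np.random.Generator) -> str:
    """Evolve ``seq`` over a branch of ``d`` expected substitutions per site.

    Each site is substituted independently with probability 1 - e^(-d); the
    replacement is drawn uniformly from the 19 other residues, so repeated
    hits at one site can revert it.
    """
    if d < 0:
        raise ValueError(f"divergence must be non-negative, got {d}")
    if d == 0 or not seq:
        return seq
    arr = np.array([_AA_INDEX[a] for a in seq], dtype=np.int64)
    p_sub = 1.0 - math.exp(-d)
    hit = rng.random(arr.size) < p_sub
    n_hit = int(hit.sum())
    if n_hit:
        # uniform over the other 19: draw 0..18 and skip the current residue
        draw = rng.integers(0, 19, size=n_hit)
        cur = arr[hit]
        arr[hit] = np.where(draw >= cur, draw + 1, draw)
    return _AA_ARRAY[arr].tobytes().decode()


def expected_pairwise_difference(d: float) -> float:
    """Expected differing-site fraction between two family members evolved
    independently to branch length ``d`` each from a shared ancestor.

    Exact under the single-hit model: with per-branch substitution
    probability p = 1 - e^(-d) and uniform replacement over the other 19
    residues, two copies agree iff both kept the ancestral residue or both
    substituted to the same residue, so
    P(differ) = 1 - (1-p)^2 - p^2/19.
    """
    if d < 0:
        raise ValueError(f"divergence must be non-negative, got {d}")
    p = 1.0 - math.exp(-d)
    return 1.0 - (1.0 - p) ** 2 - p * p / 19.0


# --- configuration and truth ------------------------------------------------

@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic multi-proteome dataset.

    ``presence_patterns`` lists, per family, the non-empty subset of
    organisms carrying the family. ``fragment_families`` flags families in
    which one organism's member is planted as a partial homolog: a full
    evolved copy embedded in unrelated sequence so that the homologous
    region is ``fragment_fraction`` of the planted protein's length.
    """

    organisms: tuple[str, ...]
    presence_patterns: tuple[frozenset[str], ...]
    members_per_organism: int = 1
    ancestral_length: tuple[int, int] = (250, 350)
    within_family_divergence: float = 0.15
    n_decoys_per_organism: int = 5
    fragment_families: tuple[int, ...] = ()
    fragment_fraction: float = 0.15
    freqs: str = "uniform"
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.organisms) < 2:
            raise ValueError("need at least 2 organisms")
        if len(set(self.organisms)) != len(self.organisms):
            raise ValueError("duplicate organism names")
        for i, pat in enumerate(self.presence_patterns):
            if not pat:
                raise ValueError(f"presence pattern {i} is empty")
            if not pat <= set(self.organisms):
                raise ValueError(f"presence pattern {i} names unknown organisms: {sorted(pat - set(self.organisms))}")
        if self.members_per_organism < 1:
            raise ValueError("members_per_organism must be positive")
        if self.within_family_divergence < 0:
            raise ValueError("within_family_divergence must be non-negative")
        if self.n_decoys_per_organism < 0:
            raise ValueError("n_decoys_per_organism must be non-negative")
        lo, hi = self.ancestral_length
        if lo < 1 or hi < lo:
            raise ValueError(f"invalid ancestral_length range {self.ancestral_length}")
        if not 0 < self.fragment_fraction <= 1:
            raise ValueError("fragment_fraction must be in (0, 1]")
        for i in self.fragment_families:
            if not 0 <= i < len(self.presence_patterns):
                raise ValueError(f"fragment family index {i} out of range")

    @property
    def n_families(self) -> int:
        return len(self.presence_patterns)


TRUTH_COLUMNS = ["protein_id", "organism", "family", "pattern", "is_fragment"]


def pattern_label(pattern: frozenset[str] | set[str]) -> str:
    return "+".join(sorted(pattern))


@dataclass
class SyntheticDataset:
    config: SyntheticConfig
    proteomes: dict[str, Proteome]
    truth: pd.DataFrame  # TRUTH_COLUMNS

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        paths: dict[str, Path] = {}
        for org, prot in self.proteomes.items():
            p = outdir / f"{org}.fasta"
            write_fasta(prot, p)
            paths[org] = p
        truth_path = outdir / "truth.tsv"
        write_tsv(self.truth, truth_path)
        paths["truth"] = truth_path
        return paths


def _family_rng(seed: int, family_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, 1, family_index]))


def generate_family(
    family_id: str,
    pattern: frozenset[str] | set[str],
    members_per_org: int,
    d: float,
    rng: np.random.Generator,
    length: int = 300,
    freqs: np.ndarray | None = None,
    fragment_organism: str | None = None,
    fragment_fraction: float = 0.15,
) -> tuple[list[tuple[str, str, str]], list[dict]]:
    """Generate one planted ortholog family.

    Returns ``(records, truth_rows)`` where each record is
    ``(organism, protein_id, sequence)``. All members derive from one
    ancestral sequence evolved independently to distance ``d``; ids follow
    ``famNNN_orgX_pM``. If ``fragment_organism`` is set, that organism's
    first member is planted as a partial homolog (full evolved copy plus
    unrelated sequence padding it to ``length_of_copy / fragment_fraction``).
    """
    if not pattern:
        raise ValueError("presence pattern must be non-empty")
    if members_per_org < 1:
        raise ValueError("members_per_org must be positive")
    if freqs is None:
        freqs = UNIFORM_FREQS
    ancestor = sample_ancestral_sequence(length, freqs, rng)
    records: list[tuple[str, str, str]] = []
    truth_rows: list[dict] = []
    for org in sorted(pattern):
        for m in range(1, members_per_org + 1):
            pid = f"{family_id}_{org}_p{m}"
            seq = evolve_sequence(ancestor, d, rng)
            is_fragment = org == fragment_organism and m == 1
            if is_fragment:
                total = int(round(len(seq) / fragment_fraction))
                pad = sample_ancestral_sequence(total - len(seq), freqs, rng)
                seq = seq + pad
            records.append((org, pid, seq))
            truth_rows.append({
                "protein_id": pid,
                "organism": org,
                "family": family_id,
                "pattern": pattern_label(pattern),
                "is_fragment": is_fragment,
            })
    return records, truth_rows


def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Generate K proteomes plus the planted-truth table for ``config``.

    Deterministic: identical config (including seed) reproduces identical
    sequences. Families are generated from child streams indexed by family,
    decoys from streams indexed by organism, so each is independent of the
    other's count.
    """
    freqs = residue_frequencies(config.freqs)
    proteomes = {org: Proteome(organism=org) for org in config.organisms}
    truth_rows: list[dict] = []

    for i, pattern in enumerate(config.presence_patterns):
        rng = _family_rng(config.seed, i)
        length = int(rng.integers(config.ancestral_length[0], config.ancestral_length[1] + 1))
        frag_org = max(sorted(pattern)) if i in config.fragment_families else None
        records, rows = generate_family(
            f"fam{i:03d}",
            pattern,
            config.members_per_organism,
            config.within_family_divergence,
            rng,
            length=length,
            freqs=freqs,
            fragment_organism=frag_org,
            fragment_fraction=config.fragment_fraction,
        )
        for org, pid, seq in records:
            proteomes[org].add(pid, seq)
        truth_rows.extend(rows)

    for j, org in enumerate(config.organisms):
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2, j]))
        for k in range(config.n_decoys_per_organism):
            length = int(rng.integers(config.ancestral_length[0], config.ancestral_length[1] + 1))
            pid = f"decoy{k:03d}_{org}"
            proteomes[org].add(pid, sample_ancestral_sequence(length, freqs, rng))
            truth_rows.append({
                "protein_id": pid,
                "organism": org,
                "family": "decoy",
                "pattern": org,
                "is_fragment": False,
            })

    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    expected = sum(len(p) * config.members_per_organism for p in config.presence_patterns)
    expected += len(config.organisms) * config.n_decoys_per_organism
    assert len(truth) == expected, "generated protein count does not match config bookkeeping"
    return SyntheticDataset(config=config, proteomes=proteomes, truth=truth)


def standard_fixture_config(seed: int = 0, organisms: tuple[str, ...] = ("orgA", "orgB", "orgC", "orgD")) -> SyntheticConfig:
    """The standard four-organism benchmark: one family per non-empty subset
    of organisms (all 2^K - 1 presence categories populated), plus three
    extra two-organism families planted as partial homologs to exercise
    coverage curation, plus unrelated decoys."""
    subsets = []
    for size in range(1, len(organisms) + 1):
        for combo in itertools.combinations(sorted(organisms), size):
            subsets.append(frozenset(combo))
    pair = frozenset(sorted(organisms)[:2])
    patterns = tuple(subsets) + (pair, pair, pair)
    frag_idx = tuple(range(len(subsets), len(subsets) + 3))
    return SyntheticConfig(
        organisms=organisms,
        presence_patterns=patterns,
        members_per_organism=1,
        n_decoys_per_organism=5,
        fragment_families=frag_idx,
        seed=seed,
    )


# --- annotations ------------------------------------------------------------

ANNOTATION_COLUMNS = ["protein_id", "term_id"]
TERM_COLUMNS = ["term_id", "name", "process_class"]


def generate_annotations(
    protein_ids: list[str],
    class_map: dict[str, str],
    enriched_terms: dict[str, list[str]],
    rng: np.random.Generator,
    enrichment_strength: float = 0.9,
    background_rate: float = 0.05,
    n_background_terms: int = 0,
    background_term_rate: float = 0.1,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Plant term annotations with known enriched terms.

    ``class_map`` maps term id -> process class (the term universe);
    ``enriched_terms`` maps a planted term id to the protein subset it is
    enriched in. Each planted term annotates its subset at rate
    ``enrichment_strength`` and the rest of the universe at
    ``background_rate``. ``n_background_terms`` additional unplanted terms
    (class "other") annotate all proteins at ``background_term_rate``.

    Returns ``(annotations, terms)`` tables.
    """
    if not class_map:
        raise ValueError("class_map must be non-empty")
    if not 0 <= enrichment_strength <= 1:
        raise ValueError("enrichment_strength must be in [0, 1]")
    if not 0 <= background_rate <= 1:
        raise ValueError("background_rate must be in [0, 1]")
    universe = list(protein_ids)
    known = set(universe)
    for term, subset in enriched_terms.items():
        if term not in class_map:
            raise ValueError(f"enriched term {term!r} missing from class_map")
        unknown = set(subset) - known
        if unknown:
            raise ValueError(f"enriched term {term!r} targets unknown proteins: {sorted(unknown)}")

    ann_rows: list[dict] = []
    for term in sorted(class_map):
        subset = set(enriched_terms.get(term, ()))
        for pid in universe:
            rate = enrichment_strength if pid in subset else background_rate
            if rate > 0 and rng.random() < rate:
                ann_rows.append({"protein_id": pid, "term_id": term})
    term_rows = [
        {"term_id": t, "name": f"{t} ({cls})", "process_class": cls}
        for t, cls in sorted(class_map.items())
    ]
    for b in range(n_background_terms):
        term = f"BG{b:04d}"
        term_rows.append({"term_id": term, "name": f"{term} (background)", "process_class": "other"})
        for pid in universe:
            if rng.random() < background_term_rate:
                ann_rows.append({"protein_id": pid, "term_id": term})
    annotations = pd.DataFrame(ann_rows, columns=ANNOTATION_COLUMNS)
    terms = pd.DataFrame(term_rows, columns=TERM_COLUMNS)
    return annotations, terms


# --- alignment simulation on a tree -----------------------------------------

def simulate_alignment_on_tree(
    newick: str,
    n_columns: int,
    rng: np.random.Generator,
    freqs: np.ndarray | None = None,
) -> dict[str, str]:
    """Simulate an ungapped alignment on a tree given in Newick.

    The root sequence is sampled from ``freqs`` and evolved down every
    branch under the single-hit substitution model, with branch lengths read
    as expected substitutions per site. Returns leaf label -> sequence.
    """
    if n_columns < 1:
        raise ValueError("n_columns must be positive")
    if freqs is None:
        freqs = UNIFORM_FREQS
    tree = dendropy.Tree.get(data=newick, schema="newick")
    root_seq = sample_ancestral_sequence(n_columns, freqs, rng)
    leaf_seqs: dict[str, str] = {}

    def descend(node, seq: str) -> None:
        for child in node.child_nodes():
            d = child.edge.length or 0.0
            child_seq = evolve_sequence(seq, d, rng)
            if child.is_leaf():
                leaf_seqs[child.taxon.label] = child_seq
            else:
                descend(child, child_seq)

    descend(tree.seed_node, root_seq)
    return leaf_seqs
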