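"""Synthetic compounds, proteins and activity tables with planted structure.

The generator emulates the shape of curated bioactivity extracts: two
entity universes (compounds as SMILES, proteins as sequences), IC50
values straddling the <100 nM / >10000 nM labeling thresholds, a
controllable positive:negative imbalance, and entity-disjoint train/test
splits. The interaction signal is planted at the token level — compounds
of one archetype share a ring scaffold and substituent habits, proteins
of one archetype share a 3-mer motif pool — so skip-gram embeddings can
genuinely recover it; nothing shortcuts the representation-learning step.

Whether a (compound, protein) pair interacts is decided by an additive
latent-affinity rule over archetypes: archetypes are ordered by binding
propensity and a pair is compatible when the summed propensity clears a
threshold (compound archetype + protein archetype <= A - 2 for A
archetypes). Compatible pairs draw IC50 log-uniformly from the potent
range, incompatible pairs from the inactive range, and a small fraction
epsilon of pairs has its range flipped to model assay noise.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from rdkit import Chem

from .curation import label_by_ic50
from .tokenizer import CompoundRecord, ProteinRecord, canonicalize_smiles

__all__ = [
    "SynthConfig",
    "SynthCompound",
    "SynthProtein",
    "Fixture",
    "generate_compounds",
    "generate_proteins",
    "generate_interactions",
    "make_fixture",
    "write_fixture",
    "derive_seed",
]

AMINO20 = "ACDEFGHIKLMNPQRSTVWY"

# archetype-specific chemistry: a shared ring scaffold, substituent pool
# and chain-atom bias per archetype (cycled if n_archetypes > 6)
_CORES = ["C1CCCCC1", "C1CCOCC1", "C1CCNCC1", "C1CCSCC1", "C1CCCC1", "C1CCOC1"]
_BRANCHES = [
    ["(Cl)", "(C)"],
    ["(Br)", "(O)"],
    ["(N)", "(C)"],
    ["(O)", "(Cl)"],
    ["(C)", "(N)"],
    ["(Br)", "(C)"],
]
_CHAIN_BIAS = [  # probabilities over chain atoms C, N, O, S
    [0.70, 0.10, 0.10, 0.10],
    [0.55, 0.25, 0.10, 0.10],
    [0.55, 0.10, 0.25, 0.10],
    [0.55, 0.10, 0.10, 0.25],
    [0.40, 0.30, 0.20, 0.10],
    [0.40, 0.10, 0.30, 0.20],
]
_CHAIN_ATOMS = ["C", "N", "O", "S"]


def derive_seed(seed: int, stage: str) -> int:
    """Stable per-stage seed fan-out (CRC32 of "stage:seed", below 2^31)."""
    return zlib.crc32(f"{stage}:{seed}".encode()) & 0x7FFFFFFF


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions of the synthetic benchmark."""

    n_compounds: int = 150
    n_proteins: int = 30
    n_archetypes: int = 3
    label_noise: float = 0.05  # fraction of pairs with flipped IC50 range
    pos_neg_ratio: float = 0.1  # positives per negative (0.1 == 1:10)
    ic50_positive_range: tuple[float, float] = (1.0, 99.0)
    ic50_negative_range: tuple[float, float] = (10001.0, 1e6)
    seq_length_range: tuple[int, int] = (90, 150)
    test_fraction: float = 0.2
    seed: int = 7

    def __post_init__(self) -> None:
        if not (0 <= self.label_noise < 0.5):
            raise ValueError("label noise must be in [0, 0.5)")
        if self.pos_neg_ratio <= 0:
            raise ValueError("positive:negative ratio must be positive")
        if not (self.ic50_positive_range[1] < 100 < 10000 < self.ic50_negative_range[0]):
            raise ValueError("IC50 ranges must respect the labeling thresholds strictly")
        if self.seq_length_range[0] < 9:
            raise ValueError("minimum protein length must be >= 9")


@dataclass(frozen=True)
class SynthCompound(CompoundRecord):
    archetype: int = 0


@dataclass(frozen=True)
class SynthProtein(ProteinRecord):
    archetype: int = 0


def _random_compound_smiles(rng: np.random.Generator, archetype: int) -> str:
    core = _CORES[archetype % len(_CORES)]
    branches = _BRANCHES[archetype % len(_BRANCHES)]
    bias = _CHAIN_BIAS[archetype % len(_CHAIN_BIAS)]
    m = int(rng.integers(5, 11))
    atoms = [
        _CHAIN_ATOMS[int(rng.choice(4, p=bias))] for _ in range(m)
    ]
    # substituents only on tetravalent carbons
    n_branch = int(rng.integers(1, 3))
    c_positions = [i for i, a in enumerate(atoms) if a == "C"]
    parts = list(atoms)
    if c_positions:
        for pos in rng.choice(c_positions, size=min(n_branch, len(c_positions)),
                              replace=False):
            parts[pos] = parts[pos] + branches[int(rng.integers(len(branches)))]
    insert_at = int(rng.integers(0, len(parts) + 1))
    parts.insert(insert_at, core)
    return "".join(parts)


def generate_compounds(
    n: int, seed: int, n_archetypes: int = 3
) -> list[SynthCompound]:
    """Deterministic list of valid archetype-tagged compounds."""
    if n < 1:
        raise ValueError("need n >= 1")
    rng = np.random.default_rng(derive_seed(seed, "compounds"))
    out = []
    for i in range(n):
        arch = i % n_archetypes
        for _attempt in range(20):
            smi = _random_compound_smiles(rng, arch)
            if Chem.MolFromSmiles(smi) is not None:
                break
        else:  # pragma: no cover - grammar is valid by construction
            raise RuntimeError("failed to generate a valid SMILES")
        out.append(
            SynthCompound(
                id=f"CMP{i:05d}",
                smiles_raw=smi,
                smiles_canonical=canonicalize_smiles(smi),
                archetype=arch,
            )
        )
    return out


def _motif_pools(rng: np.random.Generator, n_archetypes: int,
                 per_pool: int = 10) -> list[list[str]]:
    """Disjoint archetype-specific 3-mer motif pools."""
    pools: list[list[str]] = []
    seen: set[str] = set()
    for _ in range(n_archetypes):
        pool: list[str] = []
        while len(pool) < per_pool:
            mer = "".join(AMINO20[int(j)] for j in rng.integers(0, 20, size=3))
            if mer not in seen:
                seen.add(mer)
                pool.append(mer)
        pools.append(pool)
    return pools


def generate_proteins(
    n: int,
    length_range: tuple[int, int] = (90, 150),
    seed: int = 0,
    n_archetypes: int = 3,
    motif_fraction: float = 0.6,
) -> list[SynthProtein]:
    """Sequences assembled from archetype motif pools plus background 3-mers."""
    if length_range[0] < 9:
        raise ValueError("minimum length must be >= 9")
    rng = np.random.default_rng(derive_seed(seed, "proteins"))
    pools = _motif_pools(rng, n_archetypes)
    out = []
    for i in range(n):
        arch = i % n_archetypes
        L = int(rng.integers(length_range[0], length_range[1] + 1))
        blocks: list[str] = []
        while sum(len(b) for b in blocks) < L:
            if rng.random() < motif_fraction:
                blocks.append(pools[arch][int(rng.integers(len(pools[arch])))])
            else:
                blocks.append(
                    "".join(AMINO20[int(j)] for j in rng.integers(0, 20, size=3))
                )
        seq = "".join(blocks)[:L]
        out.append(SynthProtein(id=f"PRT{i:05d}", sequence=seq, archetype=arch))
    return out


def _compatible(c_arch: int, p_arch: int, n_archetypes: int) -> bool:
    return c_arch + p_arch <= n_archetypes - 2


def _log_uniform(rng, lo: float, hi: float) -> float:
    return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))


def generate_interactions(
    compounds: list[SynthCompound],
    proteins: list[SynthProtein],
    config: SynthConfig,
    seed: int | None = None,
) -> pd.DataFrame:
    """Activity table over all pairs, subsampled to the requested imbalance.

    Columns: compound_id, smiles, protein_id, sequence, ic50_nM, label,
    compatible, flipped. For non-flipped pairs, re-applying the IC50
    labeling rule reproduces the planted compatibility exactly.
    """
    rng = np.random.default_rng(
        derive_seed(seed if seed is not None else config.seed, "interactions")
    )
    rows = []
    for c in compounds:
        for p in proteins:
            compat = _compatible(c.archetype, p.archetype, config.n_archetypes)
            flipped = bool(rng.random() < config.label_noise)
            potent = compat ^ flipped
            lo, hi = (
                config.ic50_positive_range if potent else config.ic50_negative_range
            )
            ic50 = _log_uniform(rng, lo, hi)
            rows.append(
                {
                    "compound_id": c.id,
                    "smiles": c.smiles_canonical,
                    "protein_id": p.id,
                    "sequence": p.sequence,
                    "ic50_nM": ic50,
                    "label": label_by_ic50(ic50),
                    "compatible": compat,
                    "flipped": flipped,
                }
            )
    df = pd.DataFrame(rows)
    pos_idx = np.flatnonzero((df["label"] == "positive").to_numpy())
    neg_idx = np.flatnonzero((df["label"] == "negative").to_numpy())
    r = config.pos_neg_ratio
    n_pos = min(len(pos_idx), int(len(neg_idx) * r))
    if n_pos == 0:
        raise ValueError(
            f"requested ratio 1:{1 / r:g} unattainable with "
            f"{len(pos_idx)} positives / {len(neg_idx)} negatives"
        )
    n_neg = min(len(neg_idx), int(round(n_pos / r)))
    keep_pos = rng.choice(pos_idx, size=n_pos, replace=False)
    keep_neg = rng.choice(neg_idx, size=n_neg, replace=False)
    keep = np.sort(np.concatenate([keep_pos, keep_neg]))
    return df.iloc[keep].reset_index(drop=True)


@dataclass
class Fixture:
    """Ready-to-use synthetic study: entities, split tables, archetype tags."""

    config: SynthConfig
    compounds: list[SynthCompound]
    proteins: list[SynthProtein]
    train_compounds: list[SynthCompound]
    test_compounds: list[SynthCompound]
    train_proteins: list[SynthProtein]
    test_proteins: list[SynthProtein]
    train_records: pd.DataFrame
    test_records: pd.DataFrame
    mode: str

    @property
    def test_entity_ids(self) -> frozenset[str]:
        return frozenset(
            [c.id for c in self.test_compounds] + [p.id for p in self.test_proteins]
        )


def make_fixture(config: SynthConfig | None = None, mode: str = "entity_disjoint") -> Fixture:
    """Generate the full study: entities, disjoint split, labeled tables.

    ``entity_disjoint`` holds out whole compounds and proteins (test
    pairs involve only unseen entities); ``pair_disjoint`` holds out
    pairs while entities may be shared.
    """
    config = config or SynthConfig()
    if mode not in ("entity_disjoint", "pair_disjoint"):
        raise ValueError(f"unknown split mode {mode!r}")
    compounds = generate_compounds(config.n_compounds, config.seed, config.n_archetypes)
    proteins = generate_proteins(
        config.n_proteins, config.seq_length_range, config.seed, config.n_archetypes
    )
    rng = np.random.default_rng(derive_seed(config.seed, "split"))
    if mode == "entity_disjoint":
        n_ct = max(config.n_archetypes, int(round(config.test_fraction * len(compounds))))
        n_pt = max(config.n_archetypes, int(round(config.test_fraction * len(proteins))))
        if n_ct >= len(compounds) or n_pt >= len(proteins):
            raise ValueError("insufficient entities for a disjoint split")
        # stratify the holdout by archetype so both splits keep the signal
        c_test = _stratified_holdout(compounds, n_ct, rng)
        p_test = _stratified_holdout(proteins, n_pt, rng)
        c_train = [c for c in compounds if c.id not in {x.id for x in c_test}]
        p_train = [p for p in proteins if p.id not in {x.id for x in p_test}]
        train = generate_interactions(c_train, p_train, config,
                                      seed=derive_seed(config.seed, "train-pairs"))
        test = generate_interactions(c_test, p_test, config,
                                     seed=derive_seed(config.seed, "test-pairs"))
    else:
        all_pairs = generate_interactions(compounds, proteins, config)
        perm = rng.permutation(len(all_pairs))
        n_te = max(1, int(round(config.test_fraction * len(all_pairs))))
        test = all_pairs.iloc[np.sort(perm[:n_te])].reset_index(drop=True)
        train = all_pairs.iloc[np.sort(perm[n_te:])].reset_index(drop=True)
        c_train, p_train = compounds, proteins
        c_test, p_test = [], []
    return Fixture(
        config=config,
        compounds=compounds,
        proteins=proteins,
        train_compounds=c_train,
        test_compounds=c_test,
        train_proteins=p_train,
        test_proteins=p_test,
        train_records=train,
        test_records=test,
        mode=mode,
    )


def _stratified_holdout(entities, n_test: int, rng: np.random.Generator):
    by_arch: dict[int, list] = {}
    for e in entities:
        by_arch.setdefault(e.archetype, []).append(e)
    picked = []
    archs = sorted(by_arch)
    quota = {a: max(1, int(round(n_test * len(by_arch[a]) / len(entities)))) for a in archs}
    for a in archs:
        pool = by_arch[a]
        take = min(quota[a], len(pool) - 1)
        idx = rng.choice(len(pool), size=take, replace=False)
        picked.extend(pool[i] for i in sorted(idx))
    return picked


def write_fixture(fixture: Fixture, out_dir) -> dict[str, str]:
    """Emit the fixture in the same plain-text formats the real-data path
    consumes: interaction TSVs, a protein FASTA and a SMILES list."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    paths = {}
    for name, df in (("train", fixture.train_records), ("test", fixture.test_records)):
        p = os.path.join(out_dir, f"{name}_interactions.tsv")
        df.to_csv(p, sep="\t", index=False)
        paths[f"{name}_interactions"] = p
    fasta = os.path.join(out_dir, "proteins.fasta")
    with open(fasta, "w") as fh:
        for prot in fixture.proteins:
            fh.write(f">{prot.id}\n{prot.sequence}\n")
    paths["proteins_fasta"] = fasta
    smi = os.path.join(out_dir, "compounds.smi")
    with open(smi, "w") as fh:
        for c in fixture.compounds:
            fh.write(f"{c.smiles_canonical}\t{c.id}\n")
    paths["compounds_smiles"] = smi
    return paths
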