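"""Curation of raw activity tables into labeled interaction datasets.

Labels follow the activity-threshold convention for IC50 assays: pairs
with IC50 < 100 nM are positive, pairs with IC50 > 10000 nM are negative,
everything in between (and missing values) is excluded. Both thresholds
are configurable. The module also provides the redundancy filters used
to de-noise embedding corpora: Tanimoto similarity over Morgan
fingerprints for compounds and global-alignment identity for proteins,
each with a greedy > 80% clustering pass.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import Align
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator

from .tokenizer import CompoundRecord, ProteinRecord, TokenSequence, tokenize_protein, tokenize_smiles

__all__ = [
    "POSITIVE",
    "NEGATIVE",
    "EXCLUDED",
    "CorpusSpec",
    "label_by_ic50",
    "label_records",
    "drop_invalid",
    "morgan_bits",
    "tanimoto",
    "sequence_identity",
    "redundancy_filter",
    "build_corpus",
    "read_interaction_table",
    "write_labeled_table",
]

POSITIVE = "positive"
NEGATIVE = "negative"
EXCLUDED = "excluded"

#: columns of the interaction table external interface
TABLE_COLUMNS = ["compound_id", "smiles", "protein_id", "sequence", "ic50_nM"]


def label_by_ic50(
    ic50_nM: float | None,
    positive_below: float = 100.0,
    negative_above: float = 10000.0,
) -> str:
    """Label one activity value; strict inequalities, missing -> excluded."""
    if ic50_nM is None or (isinstance(ic50_nM, float) and math.isnan(ic50_nM)):
        return EXCLUDED
    if ic50_nM <= 0:
        raise ValueError(f"IC50 must be positive, got {ic50_nM}")
    if ic50_nM < positive_below:
        return POSITIVE
    if ic50_nM > negative_above:
        return NEGATIVE
    return EXCLUDED


def label_records(
    df: pd.DataFrame,
    positive_below: float = 100.0,
    negative_above: float = 10000.0,
) -> pd.DataFrame:
    """Add a ``label`` column by applying :func:`label_by_ic50` row-wise."""
    out = df.copy()
    out["label"] = [
        label_by_ic50(None if pd.isna(x) else float(x), positive_below, negative_above)
        for x in out["ic50_nM"]
    ]
    return out


def _has_carbon(smiles: str) -> bool:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return False
    return any(a.GetAtomicNum() == 6 for a in mol.GetAtoms())


def drop_invalid(df: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Remove records with missing IC50 and carbon-free (inorganic-proxy) compounds.

    Returns the retained records plus a report of counts removed per reason.
    A compound with no carbon atom is treated as inorganic; the criterion
    is a deliberate, simple proxy and is reported per record.
    """
    report = {"missing_ic50": 0, "inorganic": 0}
    keep = []
    organic_cache: dict[str, bool] = {}
    for _, row in df.iterrows():
        if pd.isna(row["ic50_nM"]):
            report["missing_ic50"] += 1
            continue
        smi = row["smiles"]
        if smi not in organic_cache:
            organic_cache[smi] = _has_carbon(smi)
        if not organic_cache[smi]:
            report["inorganic"] += 1
            continue
        keep.append(row)
    kept = pd.DataFrame(keep, columns=df.columns).reset_index(drop=True)
    return kept, report


_MORGAN = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=2048)


def morgan_bits(smiles: str, radius: int = 2, n_bits: int = 2048) -> frozenset[int]:
    """On-bit set of the circular (Morgan) fingerprint of a molecule."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    if radius == 2 and n_bits == 2048:
        gen = _MORGAN
    else:
        gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    fp = gen.GetFingerprint(mol)
    return frozenset(fp.GetOnBits())


def tanimoto(fp_a: Iterable[int], fp_b: Iterable[int]) -> float:
    """Tanimoto (Jaccard) similarity of two fingerprint bit sets.

    Two empty sets are defined as similarity 1 (identical absence of
    features); the convention matters only for degenerate fingerprints.
    """
    a, b = set(fp_a), set(fp_b)
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


_aligner = Align.PairwiseAligner()
_aligner.mode = "global"
_aligner.match_score = 1
_aligner.mismatch_score = 0
_aligner.open_gap_score = -1
_aligner.extend_gap_score = -1


def sequence_identity(seq_a: str, seq_b: str) -> float:
    """Global-alignment identity: matches / aligned columns.

    Alignment scoring is match +1, mismatch 0, linear gap -1; identity is
    then counted over all aligned columns (gap columns included in the
    denominator).
    """
    if not seq_a or not seq_b:
        raise ValueError("empty sequence")
    aln = _aligner.align(seq_a, seq_b)[0]
    counts = aln.counts()
    return counts.identities / aln.length


def redundancy_filter(
    entities: Sequence,
    similarity_fn: Callable,
    threshold: float = 0.8,
) -> list:
    """Greedy single-pass redundancy clustering in input order.

    An entity is dropped iff its similarity to an already-retained entity
    exceeds ``threshold`` (strict: similarity exactly at the threshold is
    retained). Exact duplicates are always dropped, even at threshold 1
    where similarity 1.0 would not strictly exceed it.
    """
    if not (0 < threshold <= 1):
        raise ValueError("threshold must be in (0, 1]")
    retained: list = []
    for e in entities:
        dup = any(e == r for r in retained)
        if not dup and all(similarity_fn(e, r) <= threshold for r in retained):
            retained.append(e)
    return retained


@dataclass(frozen=True)
class CorpusSpec:
    """How to assemble embedding corpora from entity inventories."""

    name: str = "corpus_all"
    dedupe: str = "none"  # "none" | "redundancy_filtered"
    exclude_entities: frozenset[str] = frozenset()
    oov_policy: str = "averaged"
    similarity_threshold: float = 0.8


def build_corpus(
    spec: CorpusSpec,
    compounds: Sequence[CompoundRecord],
    proteins: Sequence[ProteinRecord],
    atoms_only: bool = False,
) -> tuple[list[TokenSequence], list[TokenSequence], dict]:
    """Emit (compound corpus, protein corpus, provenance).

    Exclusion removes entities by id (the leak-avoidance corpus variant);
    dedupe applies the greedy >threshold redundancy filter with Tanimoto
    similarity for compounds and alignment identity for proteins.
    """
    comps = [c for c in compounds if c.id not in spec.exclude_entities]
    prots = [p for p in proteins if p.id not in spec.exclude_entities]
    n_excluded = (len(compounds) - len(comps)) + (len(proteins) - len(prots))
    n_dedup = 0
    if spec.dedupe == "redundancy_filtered":
        fps = {c.id: morgan_bits(c.smiles_canonical) for c in comps}
        kept_c = redundancy_filter(
            [c.id for c in comps],
            lambda a, b: tanimoto(fps[a], fps[b]),
            spec.similarity_threshold,
        )
        seqs = {p.id: p.sequence for p in prots}
        kept_p = redundancy_filter(
            [p.id for p in prots],
            lambda a, b: sequence_identity(seqs[a], seqs[b]),
            spec.similarity_threshold,
        )
        n_dedup = (len(comps) - len(kept_c)) + (len(prots) - len(kept_p))
        comps = [c for c in comps if c.id in set(kept_c)]
        prots = [p for p in prots if p.id in set(kept_p)]
    elif spec.dedupe != "none":
        raise ValueError(f"unknown dedupe mode {spec.dedupe!r}")
    if not comps or not prots:
        raise ValueError(f"corpus {spec.name!r} empty after filtering")
    compound_corpus = [
        tokenize_smiles(c.smiles_canonical, entity_id=c.id, atoms_only=atoms_only)
        for c in comps
    ]
    protein_corpus = [tokenize_protein(p.sequence, entity_id=p.id) for p in prots]
    provenance = {
        "variant": spec.name,
        "dedupe": spec.dedupe,
        "oov_policy": spec.oov_policy,
        "n_excluded": n_excluded,
        "n_deduplicated": n_dedup,
        "n_compounds": len(comps),
        "n_proteins": len(prots),
    }
    return compound_corpus, protein_corpus, provenance


def read_interaction_table(path, sep: str = "\t") -> pd.DataFrame:
    """Read an interaction table (TSV by default) with the standard columns.

    Missing IC50 may be an empty field or "NA".
    """
    df = pd.read_csv(path, sep=sep, na_values=["NA", ""])
    missing = [c for c in TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"interaction table missing columns: {missing}")
    return df


def write_labeled_table(df: pd.DataFrame, path, sep: str = "\t") -> None:
    df.to_csv(path, sep=sep, index=False)
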