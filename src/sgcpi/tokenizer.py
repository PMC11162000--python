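"""Tokenization of SMILES strings and protein sequences.

Both entity classes are treated as "sentences" whose "words" feed a
skip-gram embedding model: SMILES are split into atom-level tokens
(optionally keeping ring/bond/branch symbols as tokens of their own),
and protein sequences are split into consecutive non-overlapping
amino-acid 3-mers.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "TokenSequence",
    "CompoundRecord",
    "ProteinRecord",
    "canonicalize_smiles",
    "tokenize_smiles",
    "tokenize_protein",
    "SmilesParseError",
]

# Token grammar, tried in order: bracket atoms, two-letter organic-subset
# halogens, single-letter organic atoms (aromatic lowercase included),
# %dd ring closures, ring digits, then structural single characters.
_SMILES_TOKEN = re.compile(
    r"\[[^\]]*\]"
    r"|Cl|Br"
    r"|%\d{2}"
    r"|[BCNOPSFI]"
    r"|[cnops]"
    r"|\d"
    r"|[-=#$:/\\().+@]"
)

_ATOM_TOKEN = re.compile(r"\[[^\]]*\]$|Cl$|Br$|[BCNOPSFI]$|[cnops]$")

AMINO_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be parsed or tokenized."""


@dataclass(frozen=True)
class TokenSequence:
    """One tokenized entity: the "sentence" of the embedding corpus."""

    entity_id: str
    tokens: tuple[str, ...]
    modality: str  # "compound" | "protein"

    def __post_init__(self) -> None:
        if self.modality not in ("compound", "protein"):
            raise ValueError(f"unknown modality {self.modality!r}")
        if any(not t for t in self.tokens):
            raise ValueError("empty token in sequence")


@dataclass(frozen=True)
class CompoundRecord:
    id: str
    smiles_raw: str
    smiles_canonical: str


@dataclass(frozen=True)
class ProteinRecord:
    id: str
    sequence: str

    def __post_init__(self) -> None:
        bad = set(self.sequence) - AMINO_ALPHABET
        if bad:
            raise ValueError(
                f"protein {self.id}: residues outside amino-acid alphabet: {sorted(bad)}"
            )


def canonicalize_smiles(smiles: str) -> str:
    """Return the canonical SMILES for ``smiles``.

    Canonicalization is a fixed point: applying it to its own output is
    the identity. Unparseable inputs raise :class:`SmilesParseError`.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"unparseable SMILES: {smiles!r}")
    return Chem.MolToSmiles(mol)


def tokenize_smiles(
    smiles: str, entity_id: str = "", atoms_only: bool = False
) -> TokenSequence:
    """Split a SMILES string into tokens.

    Bracket atoms ``[...]`` and the two-letter halogens Cl/Br are single
    tokens. With ``atoms_only=False`` (default) ring digits, bond symbols
    and branch parentheses are emitted as their own tokens, and the
    concatenation of all tokens reproduces the input exactly. With
    ``atoms_only=True`` only atom tokens are kept.
    """
    if not smiles:
        raise SmilesParseError("empty SMILES string")
    tokens: list[str] = []
    pos = 0
    while pos < len(smiles):
        m = _SMILES_TOKEN.match(smiles, pos)
        if m is None:
            if smiles[pos] == "[":
                raise SmilesParseError(f"unmatched '[' at position {pos} in {smiles!r}")
            raise SmilesParseError(
                f"unrecognized character {smiles[pos]!r} at position {pos} in {smiles!r}"
            )
        tokens.append(m.group())
        pos = m.end()
    if atoms_only:
        tokens = [t for t in tokens if _ATOM_TOKEN.match(t)]
    return TokenSequence(entity_id=entity_id, tokens=tuple(tokens), modality="compound")


def tokenize_protein(sequence: str, entity_id: str = "") -> TokenSequence:
    """Split a protein sequence into consecutive non-overlapping 3-mers.

    Windows start at position 0 with stride 3; trailing 1-2 residues are
    dropped, so the token count is ``len(sequence) // 3``. Sequences
    shorter than 3 yield an empty token tuple with a warning.
    """
    sequence = sequence.upper()
    bad = set(sequence) - AMINO_ALPHABET
    if bad:
        raise ValueError(f"residues outside amino-acid alphabet: {sorted(bad)}")
    if len(sequence) < 3:
        warnings.warn(
            f"sequence {entity_id or sequence!r} shorter than 3 residues: no tokens",
            stacklevel=2,
        )
        return TokenSequence(entity_id=entity_id, tokens=(), modality="protein")
    n = len(sequence) // 3
    tokens = tuple(sequence[3 * i : 3 * i + 3] for i in range(n))
    return TokenSequence(entity_id=entity_id, tokens=tokens, modality="protein")
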