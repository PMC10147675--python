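"""Molecule and reaction I/O: parsing, canonicalization, tokenization.

SMILES is the interchange format throughout the package.  A ``Molecule`` is a
thin wrapper around an RDKit mol that pins a canonical isomeric SMILES as the
molecule's identity; two molecules are equal iff their canonical SMILES are
equal.  Virtual-number labels on atoms (used to mark broken bonds, e.g.
``[1SH]``) are encoded as isotope numbers, which RDKit parses and writes
natively and which survive canonicalization.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem, RDLogger

RDLogger.DisableLog("rdApp.*")


class ParseError(ValueError):
    """Raised when a SMILES string cannot be parsed."""


class TokenizationError(ValueError):
    """Raised when a string contains characters outside the SMILES alphabet."""

    def __init__(self, message: str, position: int):
        super().__init__(message)
        self.position = position


@dataclass(frozen=True)
class Molecule:
    """A parsed molecule with canonical-SMILES identity.

    Atom indices of :attr:`mol` are 0-based and stable for the life of the
    object; ``canonical_smiles`` re-parses to a graph isomorphic to ``mol``.
    """

    canonical_smiles: str
    mol: Chem.Mol = field(compare=False, hash=False, repr=False)

    @property
    def num_heavy_atoms(self) -> int:
        return self.mol.GetNumHeavyAtoms()

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.canonical_smiles


def canonicalize(smiles: str) -> Molecule:
    """Parse ``smiles`` and return a :class:`Molecule` with canonical identity.

    Stereochemistry is retained (canonical isomeric SMILES).  Virtual-number
    labels (isotope brackets) are permitted.  Raises :class:`ParseError`
    naming the offending input on failure.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ParseError(f"unparseable SMILES: {smiles!r}")
    canon = Chem.MolToSmiles(mol)
    # identity is defined on the canonical writing; re-parse so that atom
    # indices of .mol correspond to the canonical output order
    mol = Chem.MolFromSmiles(canon)
    if mol is None:  # pragma: no cover - canonical output always re-parses
        raise ParseError(f"canonical SMILES failed to re-parse: {canon!r}")
    return Molecule(canonical_smiles=canon, mol=mol)


# Regex SMILES tokenizer: bracket atoms (including virtual-number labels) are
# single tokens; two-letter elements before one-letter; "|" is the special
# separator between substructure and product-fragment sections.
_TOKEN_RE = re.compile(
    r"(\[[^\]]+\]|Br|Cl|Si|Se|se|as|b|c|n|o|s|p|B|C|N|O|S|P|F|I|"
    r"\(|\)|\.|=|#|-|\+|\\|/|:|~|@@|@|\?|>|\*|\$|\||%\d{2}|\d)"
)


@dataclass(frozen=True)
class TokenSequence:
    """An ordered token list whose concatenation reproduces the source string."""

    tokens: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.tokens)

    def __iter__(self):
        return iter(self.tokens)

    def detokenize(self) -> str:
        return "".join(self.tokens)


def tokenize(smiles: str) -> TokenSequence:
    """Tokenize a SMILES string (virtual-label brackets are single tokens)."""
    tokens: list[str] = []
    pos = 0
    for match in _TOKEN_RE.finditer(smiles):
        if match.start() != pos:
            raise TokenizationError(
                f"unrecognized character {smiles[pos]!r} at position {pos} "
                f"in {smiles!r}",
                position=pos,
            )
        tokens.append(match.group(0))
        pos = match.end()
    if pos != len(smiles):
        raise TokenizationError(
            f"unrecognized character {smiles[pos]!r} at position {pos} "
            f"in {smiles!r}",
            position=pos,
        )
    return TokenSequence(tokens=tuple(tokens))


def randomize_smiles(mol: Molecule, seed: int) -> str:
    """A randomized (non-canonical) SMILES writing of the same graph.

    Deterministic given ``seed``: atoms are renumbered by a seeded
    permutation and the molecule rewritten non-canonically.
    """
    n = mol.mol.GetNumAtoms()
    if n <= 1:
        return mol.canonical_smiles
    rng = np.random.default_rng(seed)
    perm = [int(i) for i in rng.permutation(n)]
    shuffled = Chem.RenumberAtoms(mol.mol, perm)
    return Chem.MolToSmiles(shuffled, canonical=False)


def exact_match(
    predicted: Iterable[Molecule], golden: Iterable[Molecule]
) -> bool:
    """True iff the multisets of canonical SMILES are equal."""
    return Counter(m.canonical_smiles for m in predicted) == Counter(
        m.canonical_smiles for m in golden
    )


def reactant_set_key(molecules: Iterable[Molecule]) -> tuple[str, ...]:
    """Order-free multiset key for a reactant set (sorted canonical SMILES)."""
    return tuple(sorted(m.canonical_smiles for m in molecules))


@dataclass(frozen=True)
class ReactionRecord:
    """One reaction: a set of reactant molecules and a single product."""

    reactants: tuple[Molecule, ...]
    product: Molecule
    id: str

    @property
    def reactants_smiles(self) -> str:
        return ".".join(m.canonical_smiles for m in self.reactants)


@dataclass(frozen=True)
class ReactionParseIssue:
    line_number: int
    line: str
    reason: str


def parse_reaction_smiles(line: str, record_id: str) -> list[ReactionRecord]:
    """Parse one reaction SMILES line into records (one per product).

    Accepts ``reactants>>product`` or ``reactants>reagents>product``; the
    reagent field is parsed and discarded (species that contribute no atoms
    to the product are not reactants).  Multi-product lines are split into
    one record per product sharing the reactant set.
    """
    parts = line.split(">")
    if len(parts) == 3:
        reactant_part, _reagents, product_part = parts
    else:
        raise ValueError(f"not a reaction SMILES (expected 2 '>'): {line!r}")
    if not reactant_part.strip():
        raise ValueError("no reactants (invalid record)")
    if not product_part.strip():
        raise ValueError("no product")
    reactants = tuple(
        canonicalize(s) for s in reactant_part.split(".") if s
    )
    products = [canonicalize(s) for s in product_part.split(".") if s]
    if len(products) == 1:
        return [ReactionRecord(reactants=reactants, product=products[0], id=record_id)]
    return [
        ReactionRecord(reactants=reactants, product=p, id=f"{record_id}.{i}")
        for i, p in enumerate(products)
    ]


def read_reaction_file(
    path,
) -> tuple[list[ReactionRecord], list[ReactionParseIssue]]:
    """Read one reaction SMILES per line; malformed lines are reported.

    Returns ``(records, issues)``; invalid lines (unparseable, or with no
    reactants) are collected with their line numbers, never silently dropped.
    """
    records: list[ReactionRecord] = []
    issues: list[ReactionParseIssue] = []
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line:
                continue
            try:
                records.extend(parse_reaction_smiles(line, record_id=f"L{lineno}"))
            except (ValueError, ParseError) as exc:
                issues.append(
                    ReactionParseIssue(line_number=lineno, line=line, reason=str(exc))
                )
    return records, issues


def write_reaction_file(records: Sequence[ReactionRecord], path) -> None:
    with open(path, "w") as handle:
        for record in records:
            handle.write(
                f"{record.reactants_smiles}>>{record.product.canonical_smiles}\n"
            )
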