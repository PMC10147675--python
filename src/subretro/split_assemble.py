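"""Split a molecule into a substructure and fragments joined by
virtual-number-labeled broken bonds, and merge pieces back exactly.

Every bond crossing the substructure/fragment partition is cut; both cut ends
receive (i) the same fresh virtual number and (ii) one padding hydrogen per
unit of the lost bond order, so each piece is written as a charge-neutral
closed-shell molecule rather than a radical.  Virtual numbers are encoded as
SMILES isotope labels — ``[1SH]`` is virtual atom number 1 — which RDKit
parses and writes natively and which the tokenizer treats as single tokens.
The broken bond's order is recorded so merge can remove the padding
hydrogens and restore the original bond.

Limits imposed by the labeling scheme: crossing bonds may not be aromatic or
stereo-designated (pruning guarantees this upstream), and no atom may carry
two labels, i.e. a substructure atom or a fragment atom may have at most one
crossing bond.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from rdkit import Chem

from .chem import Molecule, ParseError, canonicalize

_ORDER_TO_BOND = {
    1: Chem.BondType.SINGLE,
    2: Chem.BondType.DOUBLE,
    3: Chem.BondType.TRIPLE,
}
_BOND_TO_ORDER = {v: k for k, v in _ORDER_TO_BOND.items()}


class SplitError(ValueError):
    """The atom selection violates the split guarantees (caller bug)."""


class MergeError(ValueError):
    """The two labeled SMILES cannot be joined (invalid prediction)."""


class ChemistryError(ValueError):
    """Bond formation would violate valence; the prediction is discarded."""


@dataclass(frozen=True)
class VirtualBond:
    number: int
    substructure_atom: int  # parent atom index
    fragment_atom: int  # parent atom index
    order: int  # 1, 2 or 3


@dataclass(frozen=True)
class SplitMolecule:
    """A parent molecule partitioned into substructure and fragments.

    ``substructure_smiles`` and ``fragment_smiles`` are dot-joined labeled
    SMILES; together with ``bonds`` they reconstruct the parent exactly.
    """

    parent: Molecule
    substructure_smiles: str
    fragment_smiles: str
    bonds: tuple[VirtualBond, ...]

    @property
    def bond_orders(self) -> dict[int, int]:
        return {b.number: b.order for b in self.bonds}


def _canonical_ranks(mol: Chem.Mol) -> list[int]:
    return list(Chem.CanonicalRankAtoms(mol, breakTies=True))


def split(
    mol: Molecule,
    substructure_atoms: frozenset[int] | set[int],
    number_map: Mapping[int, int] | None = None,
) -> SplitMolecule:
    """Cut every bond crossing the partition and label both ends.

    ``number_map`` optionally maps substructure atom index -> virtual number
    (used when numbering must stay consistent with another split); by default
    crossing bonds are numbered 1..K sorted by (substructure-atom canonical
    rank, fragment-atom canonical rank).
    """
    selection = frozenset(substructure_atoms)
    parent = mol.mol
    n_atoms = parent.GetNumAtoms()
    if any(i < 0 or i >= n_atoms for i in selection):
        raise SplitError("selection contains out-of-range atom indices")

    crossing: list[tuple[int, int, int]] = []  # (sub_atom, frag_atom, order)
    sub_seen: set[int] = set()
    frag_seen: set[int] = set()
    for bond in parent.GetBonds():
        a, b = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        if (a in selection) == (b in selection):
            continue
        sub_atom, frag_atom = (a, b) if a in selection else (b, a)
        if bond.GetBondType() == Chem.BondType.AROMATIC:
            raise SplitError(
                f"aromatic bond {sub_atom}-{frag_atom} crosses the partition"
            )
        if (
            bond.GetStereo() != Chem.BondStereo.STEREONONE
            or bond.GetBondDir() != Chem.BondDir.NONE
        ):
            raise SplitError(
                f"stereo bond {sub_atom}-{frag_atom} crosses the partition"
            )
        if bond.GetBondType() not in _BOND_TO_ORDER:
            raise SplitError(f"unsupported bond type {bond.GetBondType()}")
        if sub_atom in sub_seen or frag_atom in frag_seen:
            raise SplitError(
                "an atom has two crossing bonds; one atom cannot carry two labels"
            )
        sub_seen.add(sub_atom)
        frag_seen.add(frag_atom)
        crossing.append((sub_atom, frag_atom, _BOND_TO_ORDER[bond.GetBondType()]))

    ranks = _canonical_ranks(parent)
    crossing.sort(key=lambda t: (ranks[t[0]], ranks[t[1]]))
    if number_map is None:
        numbers = {t[0]: i + 1 for i, t in enumerate(crossing)}
    else:
        numbers = dict(number_map)
        missing = [t[0] for t in crossing if t[0] not in numbers]
        if missing:
            raise SplitError(f"number_map missing crossing atoms {missing}")

    editable = Chem.RWMol(parent)
    virtual_bonds: list[VirtualBond] = []
    for sub_atom, frag_atom, order in crossing:
        number = numbers[sub_atom]
        for idx in (sub_atom, frag_atom):
            atom = editable.GetAtomWithIdx(idx)
            total_h = atom.GetTotalNumHs()
            atom.SetNumExplicitHs(total_h + order)
            atom.SetNoImplicit(True)
            atom.SetIsotope(number)
        editable.RemoveBond(sub_atom, frag_atom)
        virtual_bonds.append(
            VirtualBond(
                number=number,
                substructure_atom=sub_atom,
                fragment_atom=frag_atom,
                order=order,
            )
        )
    cut = editable.GetMol()
    try:
        Chem.SanitizeMol(cut)
    except Exception as exc:  # pragma: no cover - guarded by checks above
        raise SplitError(f"split produced an unsanitizable molecule: {exc}") from exc

    fragments = Chem.GetMolFrags(cut)
    sub_pieces: list[str] = []
    frag_pieces: list[str] = []
    for piece in fragments:
        # re-parse so each piece gets its standalone canonical writing
        # (identical labeled subgraphs then serialize identically no matter
        # which parent they were cut from)
        smiles = Chem.MolToSmiles(
            Chem.MolFromSmiles(
                Chem.MolFragmentToSmiles(cut, atomsToUse=list(piece), canonical=True)
            )
        )
        if set(piece) <= selection:
            sub_pieces.append(smiles)
        elif not (set(piece) & selection):
            frag_pieces.append(smiles)
        else:  # pragma: no cover - impossible once all crossing bonds are cut
            raise SplitError("piece straddles the partition")
    return SplitMolecule(
        parent=mol,
        substructure_smiles=".".join(sorted(sub_pieces)),
        fragment_smiles=".".join(sorted(frag_pieces)),
        bonds=tuple(virtual_bonds),
    )


def _parse_labeled(smiles: str, role: str) -> Chem.Mol | None:
    if not smiles:
        return None
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise MergeError(f"unparseable {role} SMILES: {smiles!r}")
    return mol


def infer_bond_order(
    number: int, declared_orders: Mapping[int, int] | None
) -> int:
    """The bond order to restore at a virtual number.

    Uses the recorded order when merging a known split; model-predicted
    fragments default to a single bond.
    """
    if declared_orders and number in declared_orders:
        order = declared_orders[number]
        if order not in _ORDER_TO_BOND:
            raise ChemistryError(f"unsupported bond order {order}")
        return order
    return 1


def merge(
    substructure_smiles: str,
    fragment_smiles: str,
    bond_orders: Mapping[int, int] | None = None,
) -> list[Molecule]:
    """Join labeled pieces back into full molecules.

    For each virtual number, one padding hydrogen per bond-order unit is
    removed from each partner and a bond of the declared order is created;
    labels are stripped and the canonicalized molecule set returned (each
    disconnected component one molecule).  A number present on only one side
    raises :class:`MergeError`; a valence violation raises
    :class:`ChemistryError`.
    """
    sub = _parse_labeled(substructure_smiles, "substructure")
    frag = _parse_labeled(fragment_smiles, "fragment")
    if sub is None and frag is None:
        raise MergeError("both inputs empty")
    if sub is None or frag is None:
        combined = sub if sub is not None else frag
        n_sub = combined.GetNumAtoms() if sub is not None else 0
    else:
        n_sub = sub.GetNumAtoms()
        combined = Chem.CombineMols(sub, frag)

    by_number: dict[int, dict[str, list[int]]] = {}
    for atom in combined.GetAtoms():
        label = atom.GetIsotope()
        if label:
            side = "sub" if atom.GetIdx() < n_sub else "frag"
            by_number.setdefault(label, {"sub": [], "frag": []})[side].append(
                atom.GetIdx()
            )

    editable = Chem.RWMol(combined)
    for number, sides in sorted(by_number.items()):
        if len(sides["sub"]) != 1 or len(sides["frag"]) != 1:
            raise MergeError(
                f"virtual number {number} must appear exactly once on each side "
                f"(substructure: {len(sides['sub'])}, fragment: {len(sides['frag'])})"
            )
        order = infer_bond_order(number, bond_orders)
        a, b = sides["sub"][0], sides["frag"][0]
        for idx in (a, b):
            atom = editable.GetAtomWithIdx(idx)
            explicit = atom.GetNumExplicitHs()
            if explicit < order:
                raise ChemistryError(
                    f"atom {idx} lacks {order} padding hydrogen(s) for "
                    f"virtual number {number}"
                )
            atom.SetNumExplicitHs(explicit - order)
            atom.SetIsotope(0)
        editable.AddBond(a, b, _ORDER_TO_BOND[order])
    merged = editable.GetMol()
    try:
        Chem.SanitizeMol(merged)
    except Exception as exc:
        raise ChemistryError(f"merged molecule failed sanitization: {exc}") from exc
    pieces = Chem.GetMolFrags(merged, asMols=True)
    try:
        return [canonicalize(Chem.MolToSmiles(p)) for p in pieces]
    except ParseError as exc:  # pragma: no cover - sanitized mols re-parse
        raise ChemistryError(str(exc)) from exc
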