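"""Force-field dihedral parameter linting and topology transforms.

GAFF 2.x parameter files contain dihedral entries where an identical
atom-type quadruple is assigned several distinct parameter sets with
the same multiplicity, entered non-sequentially in the file.  Typing
engines then disagree: some keep the first match, some the last, some
apply every set at once — producing different potentials from the same
force field.  This module parses AMBER and GROMACS dihedral blocks,
detects that pathology under a three-part rule (atom-type specific,
shared multiplicity with differing parameters, non-sequential entries),
and rewrites topologies under an explicit resolution policy.  It also
applies uniform partial-charge scaling to an atom selection.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, replace
from typing import Callable, Optional, Sequence

from .constants import KCAL_TO_KJ

__all__ = [
    "DihedralParam",
    "OverdefinitionGroup",
    "Atom",
    "DihedralAssignment",
    "Topology",
    "parse_dihedral_params",
    "write_dihedral_params",
    "detect_overdefined",
    "parse_topology",
    "write_topology",
    "apply_dihedral_policy",
    "scale_charges",
    "highest_barrier",
]

_AMBER_DIALECTS = ("amber-dat", "amber-frcmod")
_GROMACS_DIALECTS = ("gromacs-itp",)
WILDCARD = "X"


@dataclass(frozen=True)
class DihedralParam:
    """One proper-dihedral parameter line.

    ``barrier`` is stored in kJ/mol (AMBER kcal/mol values are
    converted at parse time, dialect recorded).  ``periodicity`` is the
    absolute multiplicity; a negative sign in an AMBER source line is a
    continuation flag (more terms follow for the same quadruple) and is
    kept in ``continuation``.
    """

    atom_types: tuple[str, str, str, str]
    divider: int
    barrier: float
    phase: float
    periodicity: int
    source_line: int
    continuation: bool = False
    dialect: str = "amber-dat"

    def __post_init__(self):
        if self.periodicity < 1:
            raise ValueError("periodicity must be >= 1 after normalization")

    @property
    def wildcard(self) -> bool:
        return any(t.upper() == WILDCARD for t in self.atom_types)

    @property
    def canonical_quadruple(self) -> tuple[str, str, str, str]:
        fwd = self.atom_types
        return min(fwd, fwd[::-1])


@dataclass(frozen=True)
class OverdefinitionGroup:
    """One over-defined dihedral: a quadruple with >= 2 disjoint
    parameter sets (each a contiguous block of source lines)."""

    canonical_quadruple: tuple[str, str, str, str]
    variants: tuple[tuple[DihedralParam, ...], ...]
    non_sequential: bool = True

    def __post_init__(self):
        if len(self.variants) < 2:
            raise ValueError("a group needs at least two variants")
        if any(p.wildcard for v in self.variants for p in v):
            raise ValueError("over-defined groups are atom-type specific")


def _canon(quad: Sequence[str]) -> tuple[str, str, str, str]:
    fwd = tuple(quad)
    return min(fwd, fwd[::-1])


def _parse_amber_line(line: str, lineno: int, dialect: str) -> Optional[DihedralParam]:
    stripped = line.strip()
    if not stripped or stripped.upper() in ("DIHE", "DIHEDRAL"):
        return None
    type_field = line[:11]
    if type_field.count("-") != 3:
        raise ValueError(f"line {lineno}: malformed atom-type field {type_field!r}")
    types = tuple(t.strip() for t in type_field.split("-"))
    if any(not t for t in types):
        raise ValueError(f"line {lineno}: empty atom type in {type_field!r}")
    rest = line[11:].split()
    if len(rest) < 4:
        raise ValueError(f"line {lineno}: expected IDIVF PK PHASE PN fields")
    try:
        divider = int(float(rest[0]))
        pk = float(rest[1])
        phase = float(rest[2])
        pn = float(rest[3])
    except ValueError:
        raise ValueError(f"line {lineno}: non-numeric dihedral fields") from None
    return DihedralParam(
        atom_types=types,  # type: ignore[arg-type]
        divider=divider,
        barrier=pk * KCAL_TO_KJ,
        phase=phase,
        periodicity=int(round(abs(pn))),
        source_line=lineno,
        continuation=pn < 0,
        dialect=dialect,
    )


def _parse_gromacs_line(line: str, lineno: int) -> Optional[DihedralParam]:
    code = line.split(";", 1)[0].strip()
    if not code or code.startswith("["):
        return None
    fields = code.split()
    if len(fields) < 5:
        raise ValueError(f"line {lineno}: too few fields for a dihedraltype")
    types = tuple(fields[:4])
    try:
        funct = int(fields[4])
    except ValueError:
        raise ValueError(f"line {lineno}: non-integer function type") from None
    if funct not in (1, 4, 9):
        raise ValueError(f"line {lineno}: unsupported dihedral function type {funct}")
    if len(fields) < 8:
        raise ValueError(f"line {lineno}: expected phase, k, multiplicity")
    try:
        phase = float(fields[5])
        k = float(fields[6])
        pn = float(fields[7])
    except ValueError:
        raise ValueError(f"line {lineno}: non-numeric dihedral parameters") from None
    return DihedralParam(
        atom_types=types,  # type: ignore[arg-type]
        divider=1,
        barrier=k,
        phase=phase,
        periodicity=int(round(abs(pn))),
        source_line=lineno,
        continuation=False,
        dialect="gromacs-itp",
    )


def parse_dihedral_params(text: str, dialect: str = "amber-dat") -> list[DihedralParam]:
    """Parse a proper-dihedral parameter block.

    Supported dialects: ``amber-dat`` / ``amber-frcmod`` (identical
    DIHE line layout: types, IDIVF, PK in kcal/mol, PHASE in degrees,
    PN with negative values as continuation flags) and ``gromacs-itp``
    (``[ dihedraltypes ]`` entries with function types 1/4/9, k already
    in kJ/mol).  Line numbers are 1-based and preserved; malformed
    lines raise ``ValueError`` naming the line.
    """
    params: list[DihedralParam] = []
    if dialect in _AMBER_DIALECTS:
        for lineno, line in enumerate(text.splitlines(), start=1):
            p = _parse_amber_line(line, lineno, dialect)
            if p is not None:
                params.append(p)
    elif dialect in _GROMACS_DIALECTS:
        in_section = "[" not in text  # raw block without headers
        for lineno, line in enumerate(text.splitlines(), start=1):
            code = line.split(";", 1)[0].strip()
            if code.startswith("["):
                in_section = code.replace(" ", "") == "[dihedraltypes]"
                continue
            if not in_section:
                continue
            p = _parse_gromacs_line(line, lineno)
            if p is not None:
                params.append(p)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return params


def write_dihedral_params(params: Sequence[DihedralParam], dialect: str) -> str:
    """Write parameter lines back out (normalized whitespace).

    parse -> write -> parse is a fixed point for both dialect families.
    """
    lines = []
    if dialect in _AMBER_DIALECTS:
        for p in params:
            types = "-".join(f"{t:<2s}" for t in p.atom_types)
            pn = -p.periodicity if p.continuation else p.periodicity
            lines.append(
                f"{types} {p.divider:4d} {p.barrier / KCAL_TO_KJ:10.5f} "
                f"{p.phase:12.3f} {float(pn):12.1f}"
            )
    elif dialect in _GROMACS_DIALECTS:
        lines.append("[ dihedraltypes ]")
        for p in params:
            t = p.atom_types
            lines.append(
                f"{t[0]:>4s} {t[1]:>4s} {t[2]:>4s} {t[3]:>4s}    9 "
                f"{p.phase:10.2f} {p.barrier:12.5f}   {p.periodicity:d}"
            )
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return "\n".join(lines) + "\n"


def _split_contiguous(params: list[DihedralParam]) -> list[tuple[DihedralParam, ...]]:
    """Split one quadruple's parameters into sets of contiguous source
    lines; a multi-term entry is one set, separated re-definitions are
    distinct sets."""
    params = sorted(params, key=lambda p: p.source_line)
    sets: list[list[DihedralParam]] = [[params[0]]]
    for prev, cur in zip(params, params[1:]):
        if cur.source_line == prev.source_line + 1:
            sets[-1].append(cur)
        else:
            sets.append([cur])
    return [tuple(s) for s in sets]


def detect_overdefined(params: Sequence[DihedralParam]) -> list[OverdefinitionGroup]:
    """Find over-defined dihedrals under the three-part rule.

    A quadruple (canonicalized over reading direction) is flagged iff
    (1) none of its entries uses a wildcard type, (2) it carries at
    least two disjoint parameter sets that share at least one
    multiplicity with differing barrier or phase, and (3) the sets are
    non-sequential, i.e. separated by unrelated lines.  Legitimate
    multi-term dihedrals (one contiguous block) and re-definitions with
    fully disjoint multiplicities are not flagged.  Output ordering is
    deterministic (sorted by quadruple).
    """
    by_quad: dict[tuple[str, str, str, str], list[DihedralParam]] = {}
    for p in params:
        by_quad.setdefault(p.canonical_quadruple, []).append(p)

    groups = []
    for quad in sorted(by_quad):
        plist = by_quad[quad]
        if any(p.wildcard for p in plist):
            continue
        sets = _split_contiguous(plist)
        if len(sets) < 2:
            continue
        conflicting = False
        for s1, s2 in itertools.combinations(sets, 2):
            per1 = {p.periodicity: p for p in s1}
            per2 = {p.periodicity: p for p in s2}
            for n in set(per1) & set(per2):
                a, b = per1[n], per2[n]
                if (
                    abs(a.barrier / a.divider - b.barrier / b.divider) > 1e-9
                    or abs(a.phase - b.phase) > 1e-9
                ):
                    conflicting = True
        if conflicting:
            groups.append(
                OverdefinitionGroup(
                    canonical_quadruple=quad,
                    variants=tuple(sets),
                    non_sequential=True,
                )
            )
    return groups


# ---------------------------------------------------------------------------
# topologies


@dataclass(frozen=True)
class Atom:
    """One `[ atoms ]` entry of a GROMACS topology."""

    index: int  # 1-based, contiguous
    type: str
    name: str
    charge: float
    mass: float
    residue: str = "MOL"

    def __post_init__(self):
        if not (self.charge == self.charge and abs(self.charge) < 1e6):
            raise ValueError("charge must be finite")


@dataclass(frozen=True)
class DihedralAssignment:
    """One `[ dihedrals ]` line: an atom-index quadruple with either a
    parameter lookup (no inline terms) or one inline term."""

    indices: tuple[int, int, int, int]
    funct: int = 9
    term: Optional[tuple[float, float, int]] = None  # phase deg, k kJ/mol, pn


@dataclass(frozen=True)
class Topology:
    """Minimal topology: atoms and proper-dihedral assignments."""

    atoms: tuple[Atom, ...]
    dihedrals: tuple[DihedralAssignment, ...] = ()

    def __post_init__(self):
        indices = [a.index for a in self.atoms]
        if indices != list(range(1, len(indices) + 1)):
            raise ValueError("atom indices must be 1-based and contiguous")
        for d in self.dihedrals:
            if any(not 1 <= i <= len(indices) for i in d.indices):
                raise ValueError(f"dihedral {d.indices} references a missing atom")

    def types_of(self, indices: Sequence[int]) -> tuple[str, ...]:
        return tuple(self.atoms[i - 1].type for i in indices)

    @property
    def net_charge(self) -> float:
        return float(sum(a.charge for a in self.atoms))


def parse_topology(text: str) -> Topology:
    """Parse the `[ atoms ]` and `[ dihedrals ]` sections of a GROMACS
    .top/.itp file (other sections are ignored)."""
    atoms: list[Atom] = []
    dihedrals: list[DihedralAssignment] = []
    section = None
    for lineno, raw in enumerate(text.splitlines(), start=1):
        code = raw.split(";", 1)[0].strip()
        if not code:
            continue
        if code.startswith("["):
            section = code.strip("[] ").lower()
            continue
        fields = code.split()
        if section == "atoms":
            if len(fields) < 8:
                raise ValueError(f"line {lineno}: atoms line needs 8 fields")
            atoms.append(
                Atom(
                    index=int(fields[0]),
                    type=fields[1],
                    residue=fields[3],
                    name=fields[4],
                    charge=float(fields[6]),
                    mass=float(fields[7]),
                )
            )
        elif section == "dihedrals":
            if len(fields) < 5:
                raise ValueError(f"line {lineno}: dihedrals line needs >= 5 fields")
            idx = tuple(int(f) for f in fields[:4])
            funct = int(fields[4])
            term = None
            if len(fields) >= 8:
                term = (float(fields[5]), float(fields[6]), int(float(fields[7])))
            dihedrals.append(DihedralAssignment(indices=idx, funct=funct, term=term))
    return Topology(atoms=tuple(atoms), dihedrals=tuple(dihedrals))


def write_topology(top: Topology, moleculetype: str = "MOL") -> str:
    """Write a minimal GROMACS topology with atoms and dihedrals."""
    lines = ["[ moleculetype ]", f"{moleculetype}   3", "", "[ atoms ]"]
    for a in top.atoms:
        lines.append(
            f"{a.index:6d} {a.type:>6s}      1 {a.residue:>6s} {a.name:>6s} "
            f"{a.index:6d} {a.charge:12.6f} {a.mass:12.5f}"
        )
    lines += ["", "[ dihedrals ]"]
    for d in top.dihedrals:
        base = " ".join(f"{i:6d}" for i in d.indices) + f" {d.funct:5d}"
        if d.term is not None:
            phase, k, pn = d.term
            base += f" {phase:10.2f} {k:12.5f} {pn:4d}"
        lines.append(base)
    return "\n".join(lines) + "\n"


def highest_barrier(
    variants: Sequence[Sequence[DihedralParam]],
) -> Sequence[DihedralParam]:
    """Default preference: the variant with the largest per-term force
    constant (the sugar-specific sets carry higher barriers than the
    general-purpose ones)."""
    return max(variants, key=lambda v: max(p.barrier / p.divider for p in v))


def apply_dihedral_policy(
    topology: Topology,
    groups: Sequence[OverdefinitionGroup],
    policy: str = "preferred-variant",
    preference: Optional[
        Callable[[Sequence[Sequence[DihedralParam]]], Sequence[DihedralParam]]
    ] = None,
) -> Topology:
    """Rewrite dihedral assignments touched by over-defined groups.

    Policies:

    * ``first-match`` — keep only the variant defined earliest in the
      parameter file (what a first-match typing engine produces);
    * ``preferred-variant`` — substitute the variant chosen by the
      ``preference`` predicate (default :func:`highest_barrier`, the
      sugar-specific choice);
    * ``all-variants`` — assign every term of every variant at once
      (the over-defining interpretation).

    Assignments are replaced in place (inline function-9 terms, k
    divided by the AMBER IDIVF); atom ordering is preserved and the
    transform is idempotent.
    """
    if policy not in ("first-match", "preferred-variant", "all-variants"):
        raise ValueError(f"unknown policy {policy!r}")
    by_quad = {g.canonical_quadruple: g for g in groups}
    pref = preference or highest_barrier

    def chosen_sets(group: OverdefinitionGroup) -> list[Sequence[DihedralParam]]:
        if policy == "first-match":
            return [min(group.variants, key=lambda v: v[0].source_line)]
        if policy == "all-variants":
            return list(group.variants)
        sel = pref(group.variants)
        matches = [v for v in group.variants if tuple(v) == tuple(sel)]
        if len(matches) != 1:
            raise ValueError(
                "preference predicate must select exactly one variant "
                f"for {group.canonical_quadruple}"
            )
        return matches

    new_dihedrals: list[DihedralAssignment] = []
    seen_quads: set[tuple[int, int, int, int]] = set()
    for d in topology.dihedrals:
        quad = _canon(topology.types_of(d.indices))
        group = by_quad.get(quad)
        if group is None:
            new_dihedrals.append(d)
            continue
        if d.indices in seen_quads:
            continue  # already rewritten at the first occurrence
        seen_quads.add(d.indices)
        for variant in chosen_sets(group):
            for p in variant:
                new_dihedrals.append(
                    DihedralAssignment(
                        indices=d.indices,
                        funct=9,
                        term=(p.phase, p.barrier / p.divider, p.periodicity),
                    )
                )
    return replace(topology, dihedrals=tuple(new_dihedrals))


def scale_charges(
    topology: Topology, selection: Sequence[int], factor: float
) -> tuple[Topology, float]:
    """Scale the partial charges of the selected atoms (1-based
    indices) by ``factor``; every other field is untouched.

    Returns the new topology and the net-charge change,
    (factor - 1) * sum of selected charges.  An empty selection is a
    warned identity.
    """
    if not (factor == factor and abs(factor) < 1e6):
        raise ValueError("scale factor must be finite")
    sel = set(int(i) for i in selection)
    if not sel:
        warnings.warn("empty charge-scaling selection; topology unchanged")
        return topology, 0.0
    if any(not 1 <= i <= len(topology.atoms) for i in sel):
        raise ValueError("selection index out of range")
    new_atoms = []
    delta = 0.0
    for a in topology.atoms:
        if a.index in sel:
            delta += (factor - 1.0) * a.charge
            a = replace(a, charge=factor * a.charge)
        new_atoms.append(a)
    return replace(topology, atoms=tuple(new_atoms)), delta
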