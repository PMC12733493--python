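"""Rigid parameterized solutes: atoms, charges, LJ parameters, bookkeeping.

The solute enters the 3D stage only through per-atom coordinates, partial
charges and Lennard-Jones parameters, plus residue labels for the
pocket/SASA analyses.  Two construction routes are supported:

* a PQR-dialect file already carrying charges and radii (optionally
  extended with per-atom sigma/epsilon columns), or
* a PDB structure (read with gemmi) combined with a flat parameter table
  and an explicit per-residue protonation specification.

Coordinates are Angstrom everywhere internally; writers convert on output
only.  All-atom completeness (hydrogens present) is the caller's
responsibility — structure repair is deliberately out of scope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .errors import InvalidModelError, MissingParameterError, ParseError

__all__ = [
    "SoluteAtom",
    "SoluteSystem",
    "ParameterTable",
    "read_pqr",
    "write_pqr",
    "read_pdb",
    "assign_parameters",
]

_SIGMA_FROM_RMIN = 2.0 / 2.0 ** (1.0 / 6.0)  # sigma = 2 r_min / 2^(1/6)


@dataclass(frozen=True)
class SoluteAtom:
    serial: int
    name: str
    element: str
    residue_name: str
    residue_number: int
    chain: str
    position: tuple[float, float, float]
    charge: float = 0.0
    sigma: float = 0.0
    epsilon: float = 0.0
    vdw_radius: float = 0.0

    def __post_init__(self):
        if not all(math.isfinite(x) for x in self.position):
            raise InvalidModelError(f"atom {self.serial}: non-finite coordinates")
        if self.sigma < 0 or self.epsilon < 0 or self.vdw_radius < 0:
            raise InvalidModelError(
                f"atom {self.serial}: sigma/epsilon/vdw_radius must be >= 0")


@dataclass
class SoluteSystem:
    """A rigid, fully parameterized solute."""

    atoms: list[SoluteAtom]
    disulfides: list[tuple[tuple[str, int], tuple[str, int]]] = field(
        default_factory=list)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.atoms:
            raise InvalidModelError("solute must contain at least one atom")
        for a, b in self.disulfides:
            if a == b:
                raise InvalidModelError(
                    f"disulfide record pairs a residue with itself: {a}")

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def positions(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float)

    @property
    def charges(self) -> np.ndarray:
        return np.array([a.charge for a in self.atoms], dtype=float)

    @property
    def sigmas(self) -> np.ndarray:
        return np.array([a.sigma for a in self.atoms], dtype=float)

    @property
    def epsilons(self) -> np.ndarray:
        return np.array([a.epsilon for a in self.atoms], dtype=float)

    @property
    def vdw_radii(self) -> np.ndarray:
        return np.array([a.vdw_radius for a in self.atoms], dtype=float)

    @property
    def net_charge(self) -> float:
        return float(self.charges.sum())

    @property
    def residues(self) -> list[tuple[str, int, str]]:
        """Unique (chain, residue_number, residue_name), in atom order."""
        seen: list[tuple[str, int, str]] = []
        for a in self.atoms:
            key = (a.chain, a.residue_number, a.residue_name)
            if key not in seen:
                seen.append(key)
        return seen

    def residue_index(self) -> np.ndarray:
        """Per-atom index into ``self.residues``."""
        order = {key: i for i, key in enumerate(self.residues)}
        return np.array([order[(a.chain, a.residue_number, a.residue_name)]
                         for a in self.atoms], dtype=int)

    def extents(self) -> tuple[np.ndarray, np.ndarray]:
        pos = self.positions
        return pos.min(axis=0), pos.max(axis=0)


# ---------------------------------------------------------------------------
# PQR dialect
# ---------------------------------------------------------------------------

def read_pqr(path) -> SoluteSystem:
    """Read a (possibly LJ-extended) PQR file.

    The accepted dialect is whitespace-delimited ATOM/HETATM records::

        ATOM serial name resName [chain] resSeq x y z charge radius
             [sigma epsilon]

    When the optional trailing LJ columns are absent, sigma is derived from
    the radius (sigma = 2 r / 2^(1/6), i.e. the radius is taken as the LJ
    r_min) and epsilon is zero.
    """
    path = Path(path)
    atoms: list[SoluteAtom] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line.split()
            if not rec or rec[0] not in ("ATOM", "HETATM"):
                continue
            # chain column is optional in PQR; detect by field count
            if len(rec) in (10, 12):
                has_chain = False
            elif len(rec) in (11, 13):
                has_chain = True
            else:
                raise ParseError(
                    f"malformed PQR record ({len(rec)} fields)",
                    path=str(path), line=lineno)
            try:
                serial = int(rec[1])
                name = rec[2]
                res_name = rec[3]
                i = 4
                chain = ""
                if has_chain:
                    chain = rec[i]
                    i += 1
                res_num = int(rec[i])
                x, y, z = (float(v) for v in rec[i + 1:i + 4])
                charge = float(rec[i + 4])
                radius = float(rec[i + 5])
                if len(rec) > i + 6:
                    sigma = float(rec[i + 6])
                    epsilon = float(rec[i + 7])
                else:
                    sigma = _SIGMA_FROM_RMIN * radius
                    epsilon = 0.0
            except (ValueError, IndexError) as exc:
                raise ParseError(f"malformed PQR record: {exc}",
                                 path=str(path), line=lineno) from None
            atoms.append(SoluteAtom(
                serial=serial, name=name, element=_guess_element(name),
                residue_name=res_name, residue_number=res_num, chain=chain,
                position=(x, y, z), charge=charge, sigma=sigma,
                epsilon=epsilon, vdw_radius=radius))
    if not atoms:
        raise ParseError("no ATOM/HETATM records found", path=str(path))
    return SoluteSystem(atoms=atoms, provenance={
        "source": str(path), "format": "pqr"})


def write_pqr(system: SoluteSystem, path, *, include_lj: bool = True) -> None:
    """Write a whitespace-delimited PQR file.

    With ``include_lj`` the per-atom sigma/epsilon are appended as two
    trailing columns (ignored by standard PQR consumers, round-tripped by
    :func:`read_pqr`).
    """
    with open(path, "w") as fh:
        fh.write("REMARK generated by rismhydra\n")
        for a in system.atoms:
            fields = [
                "ATOM", f"{a.serial:>6d}", f"{a.name:<4s}",
                f"{a.residue_name:<4s}"]
            if a.chain:
                fields.append(a.chain)
            fields += [f"{a.residue_number:>5d}",
                       f"{a.position[0]:12.6f}", f"{a.position[1]:12.6f}",
                       f"{a.position[2]:12.6f}",
                       f"{a.charge:10.6f}", f"{a.vdw_radius:9.5f}"]
            if include_lj:
                fields += [f"{a.sigma:9.5f}", f"{a.epsilon:10.6f}"]
            fh.write(" ".join(fields) + "\n")


def _guess_element(name: str) -> str:
    stripped = name.strip().lstrip("0123456789")
    if len(stripped) >= 2 and stripped[:2].upper() in (
            "CL", "BR", "NA", "MG", "ZN", "FE", "CA", "MN", "SE"):
        return stripped[:2].capitalize()
    return stripped[:1].upper() if stripped else "X"


# ---------------------------------------------------------------------------
# PDB + parameter table
# ---------------------------------------------------------------------------

def read_pdb(path, chain: str | None = None):
    """Parse a PDB file with gemmi.

    Returns ``(records, ssbonds)`` where records are
    ``(serial, name, element, residue_name, residue_number, chain, xyz)``
    tuples for the selected chain (or all chains) of the first model, and
    ssbonds are ``((chain, resnum), (chain, resnum))`` pairs from SSBOND
    connections.
    """
    import gemmi
    structure = gemmi.read_structure(str(path))
    structure.setup_entities()
    records = []
    model = structure[0]
    for ch in model:
        if chain is not None and ch.name != chain:
            continue
        for res in ch:
            for atom in res:
                records.append((
                    atom.serial, atom.name, atom.element.name,
                    res.name, res.seqid.num, ch.name,
                    (atom.pos.x, atom.pos.y, atom.pos.z)))
    ssbonds = []
    for con in structure.connections:
        if con.type == gemmi.ConnectionType.Disulf:
            a, b = con.partner1, con.partner2
            pair = ((a.chain_name, a.res_id.seqid.num),
                    (b.chain_name, b.res_id.seqid.num))
            if chain is None or (pair[0][0] == chain and pair[1][0] == chain):
                ssbonds.append(pair)
    return records, ssbonds


class ParameterTable:
    """Flat (residue, atom) -> (charge, sigma, epsilon, vdw_radius) table.

    The on-disk format is whitespace-delimited text, one entry per line::

        # residue atom charge sigma epsilon vdw_radius
        GLY  N  -0.4157  3.2500  0.1700  1.824

    so toy tables are trivial to construct in tests.
    """

    def __init__(self, entries: dict[tuple[str, str], tuple[float, float, float, float]]):
        self.entries = dict(entries)

    @classmethod
    def from_file(cls, path) -> "ParameterTable":
        entries = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                body = line.split("#", 1)[0].strip()
                if not body:
                    continue
                rec = body.split()
                if len(rec) != 6:
                    raise ParseError("parameter line needs 6 fields "
                                     "(residue atom charge sigma epsilon radius)",
                                     path=str(path), line=lineno)
                try:
                    entries[(rec[0], rec[1])] = tuple(float(v) for v in rec[2:])
                except ValueError as exc:
                    raise ParseError(str(exc), path=str(path), line=lineno)
        return cls(entries)

    def lookup(self, residue: str, atom: str):
        try:
            return self.entries[(residue, atom)]
        except KeyError:
            raise MissingParameterError(
                f"no parameters for atom {atom!r} in residue {residue!r}"
            ) from None


def assign_parameters(records, table: ParameterTable,
                      protonation: dict[tuple[str, int], str] | None = None,
                      disulfides=None, provenance: dict | None = None
                      ) -> SoluteSystem:
    """Attach charges/LJ parameters to parsed structure records.

    ``records`` is the first element of :func:`read_pdb`'s return value.
    ``protonation`` maps ``(chain, residue_number)`` to a replacement
    residue type (e.g. HIS -> HID/HIE/HIP), applied before lookup.
    Residues named in ``disulfides`` are re-typed to CYX.  Lookup failures
    raise :class:`MissingParameterError` naming the offending atom; there
    are no silent defaults.  The operation is idempotent: re-assigning onto
    its own output yields an identical system.
    """
    protonation = dict(protonation or {})
    disulfides = list(disulfides or [])
    bridged = {key for pair in disulfides for key in pair}
    atoms = []
    for serial, name, element, res_name, res_num, chain, xyz in records:
        effective = protonation.get((chain, res_num), res_name)
        if effective in ("CYS",) and (chain, res_num) in bridged:
            effective = "CYX"
        charge, sigma, epsilon, radius = table.lookup(effective, name)
        atoms.append(SoluteAtom(
            serial=serial, name=name, element=element,
            residue_name=effective, residue_number=res_num, chain=chain,
            position=tuple(xyz), charge=charge, sigma=sigma,
            epsilon=epsilon, vdw_radius=radius))
    named_disulfides = []
    res_names = {(a.chain, a.residue_number): a.residue_name for a in atoms}
    for a, b in disulfides:
        named_disulfides.append(
            ((res_names.get(a, "CYX"), a[1]), (res_names.get(b, "CYX"), b[1])))
    system = SoluteSystem(atoms=atoms, disulfides=named_disulfides,
                          provenance=dict(provenance or {}))
    system.provenance.setdefault("parameter_assignment", {
        "n_atoms": len(atoms),
        "n_residues": len(system.residues),
        "n_disulfides": len(disulfides),
        "net_charge": system.net_charge,
    })
    return system


def system_records(system: SoluteSystem):
    """Re-extract parameter-assignment records from a system (idempotence)."""
    return [(a.serial, a.name, a.element, a.residue_name, a.residue_number,
             a.chain, a.position) for a in system.atoms]
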