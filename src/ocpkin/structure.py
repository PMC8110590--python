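"""Geometry from PDB coordinate files: H-bond distances, ion contacts, RMSD.

Parsing is delegated to gemmi; atoms are re-exposed in a flat, altLoc-aware
record list so distance queries can demand an explicit conformer where
alternates exist (e.g. the 'IN'/'OUT' rotamers of an engineered tryptophan).
Hydrogen-bond distances are heavy-atom to heavy-atom; superposition uses the
Kabsch algorithm with reflections disallowed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "AtomSelection",
    "StructureModel",
    "GeometryReport",
    "read_structure",
    "read_structure_text",
    "atom_distance",
    "calpha_rmsd",
    "ion_environment",
    "kabsch_superpose",
]


@dataclass(frozen=True)
class Atom:
    serial: int
    name: str
    resname: str
    resnum: int
    chain: str
    altloc: str  # "" when unique
    occupancy: float
    xyz: tuple[float, float, float]
    element: str

    @property
    def position(self) -> np.ndarray:
        return np.array(self.xyz)


@dataclass(frozen=True)
class AtomSelection:
    """Addresses one atom: chain + residue number + atom name (+ altLoc)."""

    chain: str
    resnum: int
    atom: str
    altloc: str | None = None
    resname: str | None = None

    def __str__(self) -> str:
        alt = f".{self.altloc}" if self.altloc else ""
        return f"{self.chain}/{self.resnum}/{self.atom}{alt}"


@dataclass
class StructureModel:
    """Flat atom list parsed from a PDB file."""

    atoms: list[Atom]
    pdb_id: str = ""

    def __post_init__(self) -> None:
        seen = set()
        for a in self.atoms:
            if not all(np.isfinite(a.xyz)):
                raise ValueError(f"non-finite coordinates for atom {a.serial}")
            if not (0.0 <= a.occupancy <= 1.0):
                raise ValueError(f"occupancy outside [0, 1] for atom {a.serial}")
            key = (a.chain, a.resnum, a.name, a.altloc)
            if key in seen:
                raise ValueError(f"duplicate atom record {key}")
            seen.add(key)

    def select(self, sel: AtomSelection) -> Atom:
        """Resolve a selection to exactly one atom.

        When alternate conformers exist at the addressed atom an explicit
        altLoc is required; the error lists the candidates.
        """
        hits = [
            a
            for a in self.atoms
            if a.chain == sel.chain
            and a.resnum == sel.resnum
            and a.name == sel.atom
            and (sel.resname is None or a.resname == sel.resname)
        ]
        if sel.altloc is not None:
            hits = [a for a in hits if a.altloc == sel.altloc]
        if not hits:
            raise KeyError(f"no atom matches {sel}")
        if len(hits) > 1:
            alts = sorted(a.altloc or "' '" for a in hits)
            raise KeyError(
                f"ambiguous selection {sel}: alternate conformers {alts}; "
                "specify an altLoc"
            )
        return hits[0]

    def residue_atoms(
        self, chain: str, resnum: int, side_chain_only: bool = False
    ) -> list[Atom]:
        backbone = {"N", "CA", "C", "O", "OXT"}
        out = [a for a in self.atoms if a.chain == chain and a.resnum == resnum]
        if side_chain_only:
            out = [a for a in out if a.name not in backbone]
        return out

    def calpha_map(self, chain: str, altloc_policy: str = "best") -> dict[int, Atom]:
        """Residue number -> CA atom, keeping the highest-occupancy conformer."""
        out: dict[int, Atom] = {}
        for a in self.atoms:
            if a.chain != chain or a.name != "CA":
                continue
            prev = out.get(a.resnum)
            if prev is None or a.occupancy > prev.occupancy:
                out[a.resnum] = a
        return out

    def chains(self) -> list[str]:
        seen: list[str] = []
        for a in self.atoms:
            if a.chain not in seen:
                seen.append(a.chain)
        return seen


@dataclass
class GeometryReport:
    """Named distances and RMSD entries, all in angstroms."""

    distances: dict[str, float] = field(default_factory=dict)
    rmsd: dict[str, tuple[float, int]] = field(default_factory=dict)
    missing: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "distances_A": self.distances,
            "rmsd_A": {k: {"rmsd": v[0], "n_atoms": v[1]} for k, v in self.rmsd.items()},
            "missing": self.missing,
        }

    def summary(self) -> str:
        lines = ["Geometry report", "=" * 44]
        for label, d in self.distances.items():
            lines.append(f"{label:<34} {d:8.2f} A")
        for label, (r, n) in self.rmsd.items():
            lines.append(f"{label:<34} {r:8.3f} A over {n} atoms")
        for label in self.missing:
            lines.append(f"{label:<34}   absent")
        return "\n".join(lines)


def _from_gemmi(st: gemmi.Structure) -> StructureModel:
    atoms: list[Atom] = []
    st.setup_entities()
    model = st[0]
    for chain in model:
        for res in chain:
            for at in res:
                atoms.append(
                    Atom(
                        serial=at.serial,
                        name=at.name,
                        resname=res.name,
                        resnum=res.seqid.num,
                        chain=chain.name,
                        altloc=at.altloc if at.altloc != "\x00" else "",
                        occupancy=float(at.occ),
                        xyz=(at.pos.x, at.pos.y, at.pos.z),
                        element=at.element.name,
                    )
                )
    if not atoms:
        raise ValueError("file contains no ATOM/HETATM records")
    return StructureModel(atoms, pdb_id=st.name.upper())


def read_structure(path) -> StructureModel:
    """Parse a PDB file (ATOM/HETATM, waters included, altLocs preserved)."""
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Detect)
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"cannot parse {path}: {exc}") from exc
    return _from_gemmi(st)


def read_structure_text(text: str, name: str = "") -> StructureModel:
    """Parse PDB-format text (used for in-memory fixtures)."""
    try:
        st = gemmi.read_pdb_string(text)
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"cannot parse PDB text: {exc}") from exc
    st.name = name
    return _from_gemmi(st)


def atom_distance(
    m: StructureModel, sel_a: AtomSelection, sel_b: AtomSelection
) -> float:
    """Euclidean distance (A) between two uniquely selected atoms."""
    a = m.select(sel_a)
    b = m.select(sel_b)
    return float(np.linalg.norm(a.position - b.position))


def kabsch_superpose(
    mobile: np.ndarray, target: np.ndarray
) -> tuple[np.ndarray, float]:
    """Optimal rotation+translation of ``mobile`` onto ``target`` (no reflection).

    Returns the transformed mobile coordinates and the RMSD.
    """
    if mobile.shape != target.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("coordinate arrays must both be (n, 3)")
    mu_m = mobile.mean(axis=0)
    mu_t = target.mean(axis=0)
    P = mobile - mu_m
    Q = target - mu_t
    H = P.T @ Q
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    moved = P @ R.T + mu_t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - target) ** 2, axis=1))))
    return moved, rmsd


def calpha_rmsd(
    a: StructureModel,
    b: StructureModel,
    chain_pair: tuple[str, str] | None = None,
) -> tuple[float, int]:
    """C-alpha RMSD after Kabsch superposition.

    Residues are matched by author residue number within the chain pair
    (first chains by default); unmatched residues are dropped.
    """
    if chain_pair is None:
        chain_pair = (a.chains()[0], b.chains()[0])
    ca_a = a.calpha_map(chain_pair[0])
    ca_b = b.calpha_map(chain_pair[1])
    common = sorted(set(ca_a) & set(ca_b))
    if len(common) < 3:
        raise ValueError(f"only {len(common)} matched C-alpha atoms (need >= 3)")
    xyz_a = np.array([ca_a[i].xyz for i in common])
    xyz_b = np.array([ca_b[i].xyz for i in common])
    _, rmsd = kabsch_superpose(xyz_a, xyz_b)
    return rmsd, len(common)


def ion_environment(
    m: StructureModel,
    ion_sel: AtomSelection,
    targets: list[AtomSelection | tuple[str, int, str]],
) -> GeometryReport:
    """Distances from an ion to specific atoms or to nearest residue atoms.

    A tuple target ``(chain, resnum, label)`` measures to the nearest
    side-chain atom of that residue; an :class:`AtomSelection` measures to
    that atom exactly.  Missing targets are flagged, not fatal.
    """
    ion = m.select(ion_sel)
    report = GeometryReport()
    for tgt in targets:
        if isinstance(tgt, AtomSelection):
            label = f"{ion_sel} - {tgt}"
            try:
                at = m.select(tgt)
            except KeyError:
                report.missing.append(label)
                continue
            report.distances[label] = float(np.linalg.norm(ion.position - at.position))
        else:
            chain, resnum, label = tgt
            atoms = m.residue_atoms(chain, resnum, side_chain_only=True)
            atoms = [a for a in atoms if a.element != "H"]
            if not atoms:
                report.missing.append(label)
                continue
            d = min(float(np.linalg.norm(ion.position - a.position)) for a in atoms)
            report.distances[label] = d
    return report
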