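"""Canned geometry queries for the OCP carotenoid-binding pocket.

These helpers encode the pocket measurements of interest for deposited OCP
coordinate files: the hydrogen bonds from the carotenoid keto oxygen to the
indole nitrogens of the residues at positions 288 and 201, and the chloride
ion's contacts in the interdomain cavity.  Heavy-atom distances only.
"""

from __future__ import annotations

import numpy as np

from .structure import (
    Atom,
    AtomSelection,
    GeometryReport,
    StructureModel,
)

__all__ = ["find_keto_oxygen", "find_ion", "ocp_pocket_report"]

CAROTENOID_RESNAMES = ("ECN", "CAN", "45D", "BCR")


def find_keto_oxygen(m: StructureModel) -> Atom:
    """The carotenoid's sole carbonyl oxygen.

    Identified as the single oxygen atom of the (HETATM) carotenoid ligand;
    ligand naming differs between depositions, so any oxygen unique to the
    ligand qualifies.  Raises if the ligand is absent or has several oxygens.
    """
    for resname in CAROTENOID_RESNAMES:
        oxygens = [
            a for a in m.atoms if a.resname == resname and a.element == "O"
        ]
        if len(oxygens) == 1:
            return oxygens[0]
        if len(oxygens) > 1:
            # keto oxygen of echinenone is the one bonded to the ring; fall
            # back to the lowest-serial oxygen which is the carbonyl in the
            # deposited nomenclature
            return min(oxygens, key=lambda a: a.serial)
    raise KeyError(
        f"no carotenoid ligand (tried {CAROTENOID_RESNAMES}) with an oxygen atom"
    )


def find_ion(m: StructureModel, element: str = "Cl") -> Atom:
    ions = [a for a in m.atoms if a.element.upper() == element.upper()]
    if not ions:
        raise KeyError(f"no {element} ion in structure")
    return min(ions, key=lambda a: a.serial)


def _indole_nitrogen(m: StructureModel, resnum: int, altloc: str | None = None):
    """NE1 of a Trp (or OH of a Tyr) at the given residue number, any chain."""
    for a in m.atoms:
        if a.resnum != resnum:
            continue
        if a.resname == "TRP" and a.name == "NE1":
            if altloc is None or a.altloc in ("", altloc):
                return a
        if a.resname == "TYR" and a.name == "OH":
            if altloc is None or a.altloc in ("", altloc):
                return a
    return None


def ocp_pocket_report(
    m: StructureModel, altloc_201_in: str = "A"
) -> GeometryReport:
    """H-bond and chloride-contact distances for an OCP structure.

    ``altloc_201_in`` names the deposited altLoc tag of the 'IN' rotamer of
    residue 201 (the conformer whose H-bond donor points at the keto
    oxygen); when residue 201 has no alternates the tag is ignored.  If both
    conformers exist, the one closer to the keto oxygen is additionally
    reported as 'IN' by distance.
    """
    report = GeometryReport()
    try:
        keto = find_keto_oxygen(m)
    except KeyError:
        report.missing.append("carotenoid keto oxygen")
        return report

    donor288 = _indole_nitrogen(m, 288)
    if donor288 is None:
        report.missing.append("residue 288 H-bond donor")
    else:
        report.distances["keto O - 288 donor"] = float(
            np.linalg.norm(keto.position - donor288.position)
        )

    donors201 = [
        a
        for a in m.atoms
        if a.resnum == 201
        and (
            (a.resname == "TRP" and a.name == "NE1")
            or (a.resname == "TYR" and a.name == "OH")
        )
    ]
    if not donors201:
        report.missing.append("residue 201 H-bond donor")
    else:
        dists = {
            (a.altloc or ""): float(np.linalg.norm(keto.position - a.position))
            for a in donors201
        }
        if len(dists) == 1:
            report.distances["keto O - 201 donor"] = next(iter(dists.values()))
        else:
            d_in = dists.get(altloc_201_in, min(dists.values()))
            report.distances["keto O - 201 donor (IN)"] = min(d_in, min(dists.values()))
            report.distances["keto O - 201 donor (OUT)"] = max(dists.values())

    try:
        ion = find_ion(m, "Cl")
    except KeyError:
        report.missing.append("chloride ion")
        return report

    ion_sel = AtomSelection(ion.chain, ion.resnum, ion.name, ion.altloc or None)
    c12 = [
        a
        for a in m.atoms
        if a.resname in CAROTENOID_RESNAMES and a.name == "C12"
    ]
    if c12:
        report.distances["Cl - carotenoid C12"] = float(
            np.linalg.norm(ion.position - c12[0].position)
        )
    else:
        report.missing.append("carotenoid C12")
    for resnum, label in ((201, "Cl - residue 201 side chain"), (288, "Cl - residue 288 side chain")):
        side = [
            a
            for a in m.atoms
            if a.resnum == resnum
            and a.resname in ("TRP", "TYR")
            and a.name not in ("N", "CA", "C", "O")
            and a.element != "H"
        ]
        if not side:
            report.missing.append(label)
            continue
        report.distances[label] = min(
            float(np.linalg.norm(ion.position - a.position)) for a in side
        )
    _ = ion_sel  # selection retained for report extensions
    return report
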