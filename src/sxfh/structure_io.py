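"""Crystal structure input, symmetry expansion and emitter clusters.

Reads PDB/mmCIF through gemmi, expands the asymmetric unit to one full unit
cell, and slices out small emitter-centered clusters (one fluorescing metal
atom plus the scatterers around it) from which holograms are computed.

Conventions
-----------
* Coordinates are Cartesian Angstrom; fractional <-> Cartesian uses the
  standard crystallographic orthogonalization with ``a`` along x.
* Alternate conformations: the highest-occupancy altloc is kept, ties broken
  alphabetically by altloc identifier.
* Symmetry expansion wraps each *group* (residue) into the unit cell by its
  centroid so intra-group geometry is never broken across cell boundaries.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field

import gemmi
import numpy as np
import pandas as pd

__all__ = [
    "AtomSite", "UnitCell", "EmitterCluster", "read_structure",
    "expand_unit_cell", "extract_clusters", "form_factor",
    "assign_oec_valence", "write_cluster_table", "read_cluster_table",
    "bundled_structure_path", "OEC_VALENCE_BY_SITE",
]

#: S1-state oxidation assignment of the four Mn sites of the Mn4CaO5 cluster
#: (two Mn(III) at the dangler and its cubane partner, two Mn(IV)).
OEC_VALENCE_BY_SITE = {"MN1": "III", "MN4": "III", "MN2": "IV", "MN3": "IV"}


@dataclass
class AtomSite:
    """One atom: element, site label, Cartesian position (Angstrom)."""

    element: str
    label: str
    position: np.ndarray
    occupancy: float = 1.0
    valence_tag: str | None = None
    group: str = ""

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ValueError("position must be a 3-vector")
        if not (0.0 < self.occupancy <= 1.0):
            raise ValueError(f"occupancy must be in (0, 1], got {self.occupancy}")
        el = gemmi.Element(self.element)
        if el.atomic_number == 0:
            raise ValueError(f"unknown element symbol {self.element!r}")
        self.element = el.name


@dataclass
class UnitCell:
    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0
    space_group: str = "P 1"

    def __post_init__(self):
        if min(self.a, self.b, self.c) <= 0:
            raise ValueError("cell lengths must be positive")
        for ang in (self.alpha, self.beta, self.gamma):
            if not 0.0 < ang < 180.0:
                raise ValueError("cell angles must lie in (0, 180) degrees")

    def to_gemmi(self) -> gemmi.UnitCell:
        return gemmi.UnitCell(self.a, self.b, self.c,
                              self.alpha, self.beta, self.gamma)


@dataclass
class EmitterCluster:
    """One emitter atom plus its scatterers, with a shared relative
    mean-square displacement <u^2>_Rel (Angstrom^2)."""

    emitter: AtomSite
    scatterers: list[AtomSite] = field(default_factory=list)
    u2rel: float = 0.0

    def __post_init__(self):
        if self.u2rel < 0:
            raise ValueError("u2rel must be >= 0")
        for s in self.scatterers:
            d = np.linalg.norm(s.position - self.emitter.position)
            if d <= 0.5:
                raise ValueError(
                    f"scatterer {s.label} only {d:.2f} A from emitter")


def _gemmi_structure(source) -> gemmi.Structure:
    if isinstance(source, str) and "\n" in source:
        text = source
    elif isinstance(source, (str, os.PathLike)):
        path = os.fspath(source)
        if not os.path.exists(path):
            raise FileNotFoundError(path)
        text = open(path).read()
    else:
        raise TypeError("source must be a path or structure text")
    try:
        if text.lstrip().startswith("data_") or "_atom_site." in text:
            doc = gemmi.cif.read_string(text)
            return gemmi.make_structure_from_block(doc.sole_block())
        return gemmi.read_pdb_string(text)
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"unparseable structure file: {exc}") from exc


def read_structure(source) -> tuple[list[AtomSite], UnitCell | None]:
    """Read a PDB or mmCIF structure into atom sites plus the unit cell.

    Alternate locations are resolved to the highest-occupancy conformer
    (ties alphabetical).  Returns ``cell=None`` when the file carries no
    cell record; symmetry expansion then refuses to run.
    """
    st = _gemmi_structure(source)
    if len(st) == 0:
        raise ValueError("structure contains no models")
    model = st[0]
    atoms: list[AtomSite] = []
    for chain in model:
        for res in chain:
            best: dict[str, gemmi.Atom] = {}
            for at in res:
                prev = best.get(at.name)
                if (prev is None or at.occ > prev.occ
                        or (at.occ == prev.occ and at.altloc < prev.altloc)):
                    best[at.name] = at
            for at in best.values():
                atoms.append(AtomSite(
                    element=at.element.name,
                    label=f"{at.name}.{chain.name}",
                    position=np.array(at.pos.tolist()),
                    occupancy=min(max(at.occ, 1e-6), 1.0),
                    group=f"{chain.name}/{res.name}{res.seqid.num}",
                ))
    if not atoms:
        raise ValueError("unparseable structure file: no atom records found")
    cell: UnitCell | None = None
    gc = st.cell
    if gc.is_crystal() and not (gc.a == gc.b == gc.c == 1.0):
        cell = UnitCell(gc.a, gc.b, gc.c, gc.alpha, gc.beta, gc.gamma,
                        st.spacegroup_hm or "P 1")
    return atoms, cell


def expand_unit_cell(atoms: list[AtomSite], cell: UnitCell,
                     element_filter=None) -> list[AtomSite]:
    """All symmetry copies of the (optionally element-filtered) atoms in one
    unit cell.  Count = n_selected * space-group multiplicity; groups are
    wrapped into the cell by their centroid, keeping clusters intact."""
    if cell is None:
        raise ValueError("no unit cell present; cannot expand symmetry")
    sg = gemmi.find_spacegroup_by_name(cell.space_group)
    if sg is None:
        raise ValueError(f"unknown space group symbol {cell.space_group!r}")
    gcell = cell.to_gemmi()
    ops = list(sg.operations())

    selected = [a for a in atoms
                if element_filter is None or a.element in set(element_filter)]
    # group atoms so wrapping is per-residue, not per-atom
    groups: dict[str, list[AtomSite]] = {}
    for a in selected:
        groups.setdefault(a.group or a.label, []).append(a)

    out: list[AtomSite] = []
    for iop, op in enumerate(ops):
        rot = np.array(op.rot, dtype=float) / op.DEN
        tran = np.array(op.tran, dtype=float) / op.DEN
        for gname, gatoms in groups.items():
            frac = np.array([gcell.fractionalize(gemmi.Position(*a.position)).tolist()
                             for a in gatoms])
            new = frac @ rot.T + tran
            shift = -np.floor(new.mean(axis=0))
            new = new + shift
            for a, f in zip(gatoms, new):
                pos = gcell.orthogonalize(gemmi.Fractional(*f)).tolist()
                out.append(AtomSite(a.element, f"{a.label}#{iop}",
                                    np.array(pos), a.occupancy,
                                    a.valence_tag, f"{gname}#{iop}"))
    return out


def assign_oec_valence(atoms: list[AtomSite],
                       mapping: dict[str, str] = OEC_VALENCE_BY_SITE
                       ) -> list[AtomSite]:
    """Tag Mn sites with their oxidation state by site-name prefix."""
    for a in atoms:
        site = a.label.split(".")[0].split("#")[0]
        if site in mapping:
            a.valence_tag = mapping[site]
    return atoms


def extract_clusters(atoms: list[AtomSite], emitter_element: str = "Mn",
                     companion_elements=("Mn", "Ca", "O"),
                     grouping="group", valence_filter: str | None = None,
                     u2rel: float = 0.0) -> list[EmitterCluster]:
    """One cluster per emitter atom.

    ``grouping`` is either ``"group"`` (scatterers share the emitter's
    residue/group label) or a radius cutoff in Angstrom.  ``valence_filter``
    keeps only emitters carrying that valence tag.
    """
    companions = set(gemmi.Element(e).name for e in companion_elements)
    emitter_element = gemmi.Element(emitter_element).name
    emitters = [a for a in atoms if a.element == emitter_element
                and (valence_filter is None or a.valence_tag == valence_filter)]
    if not any(a.element == emitter_element for a in atoms):
        warnings.warn(f"no {emitter_element} emitter atoms found")
        return []
    clusters = []
    for em in emitters:
        if grouping == "group":
            pool = [a for a in atoms if a.group == em.group]
        else:
            radius = float(grouping)
            pool = [a for a in atoms
                    if np.linalg.norm(a.position - em.position) <= radius]
        scat = [a for a in pool if a.element in companions and a is not em]
        clusters.append(EmitterCluster(em, scat, u2rel=u2rel))
    return clusters


# -- scattering factors ---------------------------------------------------

def _it92_coefficients(element: str):
    el = gemmi.Element(element)
    if el.atomic_number == 0:
        raise ValueError(f"unknown element symbol {element!r}")
    it = el.it92
    if it is None:
        raise ValueError(f"no scattering-factor entry for {element!r}")
    return np.asarray(it.a, float), np.asarray(it.b, float), float(it.c)


def form_factor(element: str, q) -> np.ndarray:
    """Atomic form factor f(q) in electrons, q = 2 k sin(theta/2) in 1/A.

    Sum-of-Gaussians (International Tables 4-Gaussian parameterization)
    evaluated directly: f = sum_i a_i exp(-b_i s^2) + c with s = q / (4 pi).
    """
    q = np.asarray(q, dtype=float)
    if np.any(q < 0):
        raise ValueError("q must be >= 0")
    a, b, c = _it92_coefficients(element)
    s2 = (q / (4.0 * np.pi)) ** 2
    return np.sum(a * np.exp(-b * s2[..., None]), axis=-1) + c


# -- cluster tables -------------------------------------------------------

_TABLE_COLS = ["label", "element", "x", "y", "z", "occupancy", "valence_tag"]


def write_cluster_table(atoms: list[AtomSite], path) -> None:
    rows = [{"label": a.label, "element": a.element, "x": a.position[0],
             "y": a.position[1], "z": a.position[2],
             "occupancy": a.occupancy, "valence_tag": a.valence_tag or ""}
            for a in atoms]
    pd.DataFrame(rows, columns=_TABLE_COLS).to_csv(path, index=False)


def read_cluster_table(path) -> list[AtomSite]:
    df = pd.read_csv(path, keep_default_na=False)
    return [AtomSite(r.element, r.label, np.array([r.x, r.y, r.z]),
                     float(r.occupancy), r.valence_tag or None)
            for r in df.itertuples()]


def bundled_structure_path() -> str:
    """Path of the bundled synthetic Mn4CaO5 stand-in structure."""
    return os.path.join(os.path.dirname(__file__), "data", "oec_synthetic.pdb")
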