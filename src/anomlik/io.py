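"""Readers and writers: MTZ, TSV reflection dialect, PDB models, CCP4 maps, YAML.

MTZ column labels follow CCP4 conventions — F(+)/SIGF(+)/F(-)/SIGF(-) for
Bijvoet pairs, FB/PHIB/FOM for centroid output, HLA..HLD for
Hendrickson-Lattman export.  The plain-text dialect is a TSV with columns
``h k l fplus sigplus fminus sigminus``.  PDB carries no anomalous
scattering fields, so f'/f'' are supplied via configuration on read.
"""

from __future__ import annotations

import os

import gemmi
import numpy as np
import pandas as pd
import yaml

from .crystal import AtomSite, ComplexSF, CrystalModel, RealMap, ReflectionSet, UnitCell
from .simulate import DEFAULT_ANOMALOUS, ObservedData

__all__ = [
    "write_reflections_tsv", "read_reflections_tsv",
    "write_reflections_mtz", "read_reflections_mtz",
    "write_phases_mtz",
    "write_model", "read_model",
    "write_ccp4_map",
    "write_scenario_yaml", "read_scenario_yaml",
]

TSV_COLUMNS = ["h", "k", "l", "fplus", "sigplus", "fminus", "sigminus"]


def _refl_from_miller(miller: np.ndarray, cell: UnitCell) -> ReflectionSet:
    return ReflectionSet(miller, cell.d_spacing(miller), cell)


def write_reflections_tsv(path: str, data: ObservedData) -> None:
    df = pd.DataFrame({
        "h": data.refl.miller[:, 0], "k": data.refl.miller[:, 1],
        "l": data.refl.miller[:, 2],
        "fplus": data.f_plus, "sigplus": data.sig_plus,
        "fminus": data.f_minus, "sigminus": data.sig_minus,
    })
    cell = data.refl.cell
    with open(path, "w") as fh:
        fh.write(f"# cell {cell.a:.6f} {cell.b:.6f} {cell.c:.6f} "
                 f"{cell.alpha:.6f} {cell.beta:.6f} {cell.gamma:.6f}\n")
        fh.write("# spacegroup P1\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.17g")


def read_reflections_tsv(path: str, cell: UnitCell | None = None) -> ObservedData:
    header_cell = None
    with open(path) as fh:
        for line in fh:
            if line.startswith("# cell"):
                header_cell = UnitCell(*[float(x) for x in line.split()[2:8]])
            elif not line.startswith("#"):
                break
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in TSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"TSV is missing required columns {missing}; "
                         f"expected {TSV_COLUMNS}")
    cell = cell or header_cell
    if cell is None:
        raise ValueError("no unit cell in TSV header and none supplied")
    miller = df[["h", "k", "l"]].to_numpy(dtype=int)
    refl = _refl_from_miller(miller, cell)
    return ObservedData(refl, df["fplus"].to_numpy(float),
                        df["sigplus"].to_numpy(float),
                        df["fminus"].to_numpy(float),
                        df["sigminus"].to_numpy(float))


def write_reflections_mtz(path: str, data: ObservedData) -> None:
    mtz = gemmi.Mtz(with_base=True)
    mtz.spacegroup = gemmi.SpaceGroup("P 1")
    mtz.set_cell_for_all(data.refl.cell.to_gemmi())
    mtz.add_dataset("anomlik")
    for label, typ in [("F(+)", "G"), ("SIGF(+)", "L"),
                       ("F(-)", "G"), ("SIGF(-)", "L")]:
        mtz.add_column(label, typ)
    block = np.column_stack([
        data.refl.miller.astype(float), data.f_plus, data.sig_plus,
        data.f_minus, data.sig_minus,
    ]).astype(np.float32)
    mtz.set_data(block)
    mtz.write_to_file(path)


def read_reflections_mtz(path: str, column_map: dict | None = None) -> ObservedData:
    column_map = column_map or {"fplus": "F(+)", "sigplus": "SIGF(+)",
                                "fminus": "F(-)", "sigminus": "SIGF(-)"}
    mtz = gemmi.read_mtz_file(path)
    labels = [c.label for c in mtz.columns]
    missing = [lbl for lbl in column_map.values() if lbl not in labels]
    if missing:
        raise ValueError(f"MTZ is missing columns {missing}; has {labels}")
    arr = np.array(mtz, copy=True)
    cols = {lbl: arr[:, i] for i, lbl in enumerate(labels)}
    c = mtz.cell
    cell = UnitCell(c.a, c.b, c.c, c.alpha, c.beta, c.gamma)
    miller = np.column_stack([cols["H"], cols["K"], cols["L"]]).astype(int)
    refl = _refl_from_miller(miller, cell)
    return ObservedData(refl, cols[column_map["fplus"]].astype(float),
                        cols[column_map["sigplus"]].astype(float),
                        cols[column_map["fminus"]].astype(float),
                        cols[column_map["sigminus"]].astype(float))


def write_phases_mtz(path: str, data: ObservedData, best: ComplexSF,
                     fom: np.ndarray, hl=None) -> None:
    """Centroid coefficients (FB/PHIB/FOM) and optional HL coefficients."""
    mtz = gemmi.Mtz(with_base=True)
    mtz.spacegroup = gemmi.SpaceGroup("P 1")
    mtz.set_cell_for_all(data.refl.cell.to_gemmi())
    mtz.add_dataset("anomlik")
    cols = [("FB", "F"), ("PHIB", "P"), ("FOM", "W")]
    arrays = [best.amplitude, best.phase, fom]
    if hl is not None:
        for lbl, arr in zip(["HLA", "HLB", "HLC", "HLD"],
                            [hl.a, hl.b, hl.c, hl.d]):
            cols.append((lbl, "A"))
            arrays.append(arr)
    for label, typ in cols:
        mtz.add_column(label, typ)
    block = np.column_stack([data.refl.miller.astype(float)] + arrays)
    mtz.set_data(block.astype(np.float32))
    mtz.write_to_file(path)


def write_model(path: str, model: CrystalModel) -> None:
    st = gemmi.Structure()
    st.cell = model.cell.to_gemmi()
    st.spacegroup_hm = "P 1"
    md = gemmi.Model("1")
    chain = gemmi.Chain("A")
    for i, a in enumerate(model.atoms):
        res = gemmi.Residue()
        res.name = "ANO" if a.role == "anomalous" else "GLY"
        res.seqid = gemmi.SeqId(i + 1, " ")
        res.het_flag = "H" if a.role == "anomalous" else "A"
        atom = gemmi.Atom()
        atom.name = a.element.upper()
        atom.element = gemmi.Element(a.element)
        xyz = model.cell.orthogonalize(a.frac_xyz)
        atom.pos = gemmi.Position(*xyz)
        atom.occ = a.occupancy
        atom.b_iso = a.b_iso
        res.add_atom(atom)
        chain.add_residue(res)
    md.add_chain(chain)
    st.add_model(md)
    doc = st.make_pdb_string()
    with open(path, "w") as fh:
        fh.write(doc)


def read_model(path: str, anomalous_overrides: dict | None = None) -> CrystalModel:
    """Read ATOM/HETATM records; f'/f'' per element from configuration.

    ``anomalous_overrides``: element -> (f_prime, f_double_prime); elements
    present there (or in the built-in anomalous defaults via residue name
    ANO / HETATM flag) become substructure atoms.
    """
    st = gemmi.read_structure(path)
    c = st.cell
    cell = UnitCell(c.a, c.b, c.c, c.alpha, c.beta, c.gamma)
    overrides = anomalous_overrides or {}
    atoms = []
    for md in st:
        for chain in md:
            for res in chain:
                for atom in res:
                    el = atom.element.name
                    frac = cell.fractionalize(
                        np.array([atom.pos.x, atom.pos.y, atom.pos.z]))
                    anomalous = res.name == "ANO" or res.het_flag == "H" \
                        or el in overrides
                    if anomalous:
                        fp, fpp = overrides.get(el, DEFAULT_ANOMALOUS.get(el, (0.0, 0.0)))
                        atoms.append(AtomSite(el, frac, atom.occ, atom.b_iso,
                                              fp, fpp, "anomalous"))
                    else:
                        atoms.append(AtomSite(el, frac, atom.occ, atom.b_iso))
        break
    if not atoms:
        raise ValueError(f"no atoms read from {path}")
    return CrystalModel(cell, atoms)


def write_ccp4_map(path: str, rmap: RealMap) -> None:
    grid = gemmi.FloatGrid(*rmap.values.shape)
    grid.set_unit_cell(rmap.cell.to_gemmi())
    grid.spacegroup = gemmi.SpaceGroup("P 1")
    arr = np.array(grid, copy=False)
    arr[...] = rmap.values.astype(np.float32)
    ccp4 = gemmi.Ccp4Map()
    ccp4.grid = grid
    ccp4.update_ccp4_header()
    ccp4.write_ccp4_map(path)


def write_scenario_yaml(path: str, scenario: dict) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(scenario, fh, sort_keys=False)


def read_scenario_yaml(path: str) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
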