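"""Post-processing of thin-filament regulatory-unit coordinate models.

Operates on multi-chain structures (actin, tropomyosin, and the troponin
complex) annotated with a chain-role map, and computes the distance
statistics used to compare wild-type and variant regulatory units:
frame-averaged structures, Ca2+-site coordination distances, the
inhibitory-peptide-to-actin distance, and cTnC-cTnI contact-difference
maps.  PDB input/output goes through Biopython.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio.Data.IUPACData import atom_weights
from Bio.PDB import PDBParser

__all__ = [
    "StructureModel",
    "ContactDiffMap",
    "average_structure",
    "inhibitory_peptide_actin_distance",
    "ion_coordination_distances",
    "contact_diff_map",
]

ATOM_COLUMNS = ["chain", "resnum", "resname", "atom", "element", "x", "y", "z", "mass"]

#: cTnI inhibitory-peptide residue window (inclusive)
INHIBITORY_PEPTIDE = (137, 147)


def _element_mass(element: str) -> float:
    try:
        return float(atom_weights[element.capitalize()])
    except KeyError:
        warnings.warn(f"unknown element {element!r}; assuming carbon mass",
                      UserWarning, stacklevel=2)
        return float(atom_weights["C"])


@dataclass
class StructureModel:
    """Annotated atomic coordinates of one regulatory-unit model.

    ``atoms`` is a tidy table with one row per atom (chain, residue
    number/name, atom name, element, x/y/z in Angstrom, mass in Da);
    ``chain_roles`` maps each chain id to its biological role
    (``cTnC``, ``cTnI``, ``Tm``, ``actin``, ``ion``).
    """

    atoms: pd.DataFrame
    chain_roles: dict[str, str] = field(default_factory=dict)
    name: str = ""

    def __post_init__(self):
        missing = set(ATOM_COLUMNS) - set(self.atoms.columns)
        if missing:
            raise ValueError(f"atom table is missing columns {sorted(missing)}")
        xyz = self.atoms[["x", "y", "z"]].to_numpy(dtype=float)
        if not np.all(np.isfinite(xyz)):
            raise ValueError("non-finite coordinates in structure")
        referenced = set(self.atoms["chain"].unique())
        unmapped = referenced - set(self.chain_roles)
        if self.chain_roles and unmapped:
            raise ValueError(f"chains without a role in the chain-role map: "
                             f"{sorted(unmapped)}")
        dup = self.atoms.duplicated(subset=["chain", "resnum", "atom"])
        if dup.any():
            raise ValueError("duplicate (chain, residue, atom) records")

    # ---- constructors -------------------------------------------------
    @classmethod
    def from_pdb(cls, path: str | Path, chain_roles: dict[str, str] | None = None,
                 roles_yaml: str | Path | None = None) -> "StructureModel":
        """Read a PDB file; chain roles come from a dict or a YAML sidecar."""
        if roles_yaml is not None:
            with open(roles_yaml) as fh:
                chain_roles = dict(yaml.safe_load(fh))
        parser = PDBParser(QUIET=True)
        struct = parser.get_structure(Path(path).stem, str(path))
        model = next(iter(struct))
        rows = []
        for chain in model:
            for res in chain:
                for atom in res:
                    x, y, z = atom.coord
                    rows.append((chain.id, res.id[1], res.resname.strip(),
                                 atom.get_name(), atom.element or "C",
                                 float(x), float(y), float(z),
                                 float(atom.mass)))
        atoms = pd.DataFrame(rows, columns=ATOM_COLUMNS)
        return cls(atoms=atoms, chain_roles=chain_roles or {},
                   name=Path(path).stem)

    def to_pdb(self, path: str | Path) -> None:
        """Write the structure as a minimal single-model PDB file."""
        with open(path, "w") as fh:
            for i, row in enumerate(self.atoms.itertuples(), start=1):
                record = "HETATM" if self.chain_roles.get(row.chain) == "ion" \
                    else "ATOM"
                name = row.atom if len(row.atom) >= 4 else f" {row.atom:<3s}"
                fh.write(
                    f"{record:<6s}{i:>5d} {name:<4s} {row.resname:<3s} "
                    f"{row.chain:1s}{row.resnum:>4d}    "
                    f"{row.x:8.3f}{row.y:8.3f}{row.z:8.3f}"
                    f"{1.0:6.2f}{0.0:6.2f}          "
                    f"{row.element.upper():>2s}\n"
                )
            fh.write("END\n")

    # ---- selections ---------------------------------------------------
    def chains_with_role(self, role: str) -> list[str]:
        return sorted(c for c, r in self.chain_roles.items() if r == role)

    def coords(self, mask=None) -> np.ndarray:
        df = self.atoms if mask is None else self.atoms[mask]
        return df[["x", "y", "z"]].to_numpy(dtype=float)

    def select_one(self, chain: str, resnum: int, atom: str) -> np.ndarray:
        """Coordinates of exactly one atom; raises if empty or ambiguous."""
        m = ((self.atoms["chain"] == chain) & (self.atoms["resnum"] == resnum)
             & (self.atoms["atom"] == atom))
        n = int(m.sum())
        if n != 1:
            raise KeyError(
                f"selector (chain={chain!r}, resnum={resnum}, atom={atom!r}) "
                f"matched {n} atoms; expected exactly 1"
            )
        return self.coords(m)[0]

    def center_of_mass(self, chain: str) -> np.ndarray:
        sub = self.atoms[self.atoms["chain"] == chain]
        if sub.empty:
            raise KeyError(f"no atoms in chain {chain!r}")
        w = sub["mass"].to_numpy(dtype=float)
        return np.average(sub[["x", "y", "z"]].to_numpy(dtype=float),
                          axis=0, weights=w)

    def transformed(self, R: np.ndarray | None = None,
                    t: np.ndarray | None = None) -> "StructureModel":
        """Copy with a rigid rotation R and/or translation t applied."""
        xyz = self.coords()
        if R is not None:
            xyz = xyz @ np.asarray(R, dtype=float).T
        if t is not None:
            xyz = xyz + np.asarray(t, dtype=float)
        atoms = self.atoms.copy()
        atoms[["x", "y", "z"]] = xyz
        return StructureModel(atoms=atoms, chain_roles=dict(self.chain_roles),
                              name=self.name)


@dataclass
class ContactDiffMap:
    """Variant-minus-WT distances for cTnC-cTnI pairs in WT contact.

    ``pairs`` has one row per (cTnC residue, cTnI residue) pair whose WT
    distance was <= ``cutoff`` Angstrom, with columns resC, resI, d_wt,
    d_variant, delta.  Positive delta: the residues moved apart in the
    variant; negative: they moved closer.
    """

    pairs: pd.DataFrame
    cutoff: float
    metric: str = "CA"

    def to_matrix(self) -> pd.DataFrame:
        """Pivot the deltas to a (resC x resI) matrix (NaN where no pair)."""
        return self.pairs.pivot(index="resC", columns="resI", values="delta")


# ---- operations -------------------------------------------------------

def average_structure(frames: list[StructureModel]) -> StructureModel:
    """Per-atom arithmetic mean of coordinates across identically-ordered frames."""
    if not frames:
        raise ValueError("need at least one frame")
    ref = frames[0]
    key_cols = ["chain", "resnum", "atom"]
    ref_keys = ref.atoms[key_cols]
    acc = np.zeros((len(ref.atoms), 3))
    for k, fr in enumerate(frames):
        if len(fr.atoms) != len(ref.atoms) or \
                not fr.atoms[key_cols].equals(ref_keys):
            raise ValueError(f"frame {k} atom identity/order differs from frame 0")
        acc += fr.coords()
    atoms = ref.atoms.copy()
    atoms[["x", "y", "z"]] = acc / len(frames)
    return StructureModel(atoms=atoms, chain_roles=dict(ref.chain_roles),
                          name=f"{ref.name}_avg{len(frames)}")


def _residue_coords(s: StructureModel, chain: str, metric: str) -> pd.DataFrame:
    """One reference point per residue of a chain (CA or center of mass)."""
    sub = s.atoms[s.atoms["chain"] == chain]
    if metric == "CA":
        sub = sub[sub["atom"] == "CA"]
        out = sub[["resnum", "x", "y", "z"]].copy()
    elif metric == "com":
        rows = []
        for resnum, grp in sub.groupby("resnum"):
            w = grp["mass"].to_numpy(dtype=float)
            c = np.average(grp[["x", "y", "z"]].to_numpy(dtype=float),
                           axis=0, weights=w)
            rows.append((resnum, *c))
        out = pd.DataFrame(rows, columns=["resnum", "x", "y", "z"])
    else:
        raise ValueError("metric must be 'CA' or 'com'")
    return out.sort_values("resnum").reset_index(drop=True)


def inhibitory_peptide_actin_distance(
    s: StructureModel, residues: tuple[int, int] = INHIBITORY_PEPTIDE
) -> float:
    """Mean distance from cTnI inhibitory-peptide CA atoms to the nearest actin COM.

    For each actin chain, the mean of the CA-to-center-of-mass distances
    over cTnI residues ``residues[0]``..``residues[1]`` is computed; the
    actin monomer with the smallest mean is selected (ties broken by chain
    id order) and its mean distance returned, in Angstrom.
    """
    tni_chains = s.chains_with_role("cTnI")
    actin_chains = s.chains_with_role("actin")
    if not tni_chains:
        raise KeyError("no chain with role 'cTnI' in the chain-role map")
    if not actin_chains:
        raise KeyError("no chain with role 'actin' in the chain-role map")
    chain = tni_chains[0]
    lo, hi = residues
    wanted = list(range(lo, hi + 1))
    sub = s.atoms[(s.atoms["chain"] == chain) & (s.atoms["atom"] == "CA")
                  & (s.atoms["resnum"].isin(wanted))]
    missing = sorted(set(wanted) - set(sub["resnum"]))
    if missing:
        raise KeyError(
            f"cTnI chain {chain!r} is missing CA atoms for residues {missing}"
        )
    ca = sub.sort_values("resnum")[["x", "y", "z"]].to_numpy(dtype=float)
    best: tuple[float, str] | None = None
    for ac in actin_chains:  # sorted: ties resolve to the first chain id
        com = s.center_of_mass(ac)
        mean_d = float(np.mean(np.linalg.norm(ca - com, axis=1)))
        if best is None or mean_d < best[0]:
            best = (mean_d, ac)
    return best[0]


def ion_coordination_distances(
    s: StructureModel,
    ion: tuple[str, int, str],
    atoms: list[tuple[str, int, str]],
) -> list[float]:
    """Distances from one ion to each named coordinating atom, in input order."""
    ion_xyz = s.select_one(*ion)
    return [float(np.linalg.norm(s.select_one(*sel) - ion_xyz))
            for sel in atoms]


def contact_diff_map(
    wt: StructureModel,
    variant: StructureModel,
    cutoff: float = 10.0,
    metric: str = "CA",
) -> ContactDiffMap:
    """Variant-minus-WT cTnC-cTnI residue-pair distance differences.

    All cTnC-cTnI residue-pair distances are computed in the WT structure;
    pairs at or below ``cutoff`` Angstrom define the contact set (the pair
    set depends only on WT).  The same pairs are measured in the variant
    and the per-pair difference d_variant - d_wt returned.
    """

    def chain_of(s: StructureModel, role: str) -> str:
        chains = s.chains_with_role(role)
        if not chains:
            raise KeyError(f"no chain with role {role!r}")
        return chains[0]

    cw = _residue_coords(wt, chain_of(wt, "cTnC"), metric)
    iw = _residue_coords(wt, chain_of(wt, "cTnI"), metric)
    cv = _residue_coords(variant, chain_of(variant, "cTnC"), metric)
    iv = _residue_coords(variant, chain_of(variant, "cTnI"), metric)

    for label, w_res, v_res in (("cTnC", cw, cv), ("cTnI", iw, iv)):
        missing = sorted(set(w_res["resnum"]) - set(v_res["resnum"]))
        if missing:
            raise KeyError(f"{label} residues present in WT but absent in "
                           f"variant: {missing}")

    def dist_matrix(a: pd.DataFrame, b: pd.DataFrame) -> np.ndarray:
        pa = a[["x", "y", "z"]].to_numpy(dtype=float)
        pb = b[["x", "y", "z"]].to_numpy(dtype=float)
        return np.linalg.norm(pa[:, None, :] - pb[None, :, :], axis=2)

    d_wt = dist_matrix(cw, iw)
    cv_idx = cv.set_index("resnum").loc[cw["resnum"]].reset_index()
    iv_idx = iv.set_index("resnum").loc[iw["resnum"]].reset_index()
    d_var = dist_matrix(cv_idx, iv_idx)

    ic, ii = np.nonzero(d_wt <= cutoff)
    pairs = pd.DataFrame({
        "resC": cw["resnum"].to_numpy()[ic],
        "resI": iw["resnum"].to_numpy()[ii],
        "d_wt": d_wt[ic, ii],
        "d_variant": d_var[ic, ii],
    })
    pairs["delta"] = pairs["d_variant"] - pairs["d_wt"]
    return ContactDiffMap(pairs=pairs, cutoff=cutoff, metric=metric)
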