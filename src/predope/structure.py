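"""Structure-based descriptors for rationalising per-residue PREs.

Two per-tryptophan descriptors are computed from a PDB model of the
assembly:

* ``d_rss`` — the root-sum-square dipolar coupling between the ¹⁹F site
  and all back-exchangeable protons, √(Σⱼ d(F,Hⱼ)²).  It approximates the
  strength of the local dipolar network and hence the efficiency of spin
  diffusion, which spreads paramagnetic relaxation through the protein.
* SASA — the solvent-accessible surface area of the tryptophan, a proxy
  for how closely a dissolved paramagnetic compound can approach the site.

The fluorine of 5-fluorotryptophan sits on the 5-position of the indole
ring; its position is approximated by the CZ3 carbon itself (the ~1.3 Å
C–F bond offset is below the interpretive precision of the descriptor).
"Back-exchangeable protons" are the backbone amide H plus hydrogens bound
to side-chain N, O or S — the set that is reprotonated when a
perdeuterated protein is exchanged into H₂O buffer.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .sbm import CONSTANTS, ANGSTROM

__all__ = [
    "StructureModel",
    "StructureDescriptors",
    "ProtonSet",
    "read_pdb",
    "select_exchangeable_protons",
    "dipolar_coupling",
    "d_rss",
    "sasa",
    "residue_sasa",
    "compute_descriptors",
    "correlate_descriptors",
]

VDW_RADII = {"H": 1.2, "C": 1.7, "N": 1.55, "O": 1.52, "S": 1.8, "F": 1.47}
PROBE_RADIUS = 1.4  # Å
SASA_POINTS = 960

# side-chain heavy atoms carrying exchangeable hydrogens, with proton counts
_SIDECHAIN_EXCHANGEABLE: dict[str, dict[str, int]] = {
    "SER": {"OG": 1},
    "THR": {"OG1": 1},
    "TYR": {"OH": 1},
    "CYS": {"SG": 1},
    "LYS": {"NZ": 3},
    "ARG": {"NE": 1, "NH1": 2, "NH2": 2},
    "ASN": {"ND2": 2},
    "GLN": {"NE2": 2},
    "HIS": {"ND1": 1, "NE2": 1},
    "TRP": {"NE1": 1},
}


@dataclass
class StructureModel:
    """A parsed structure: a biotite AtomArray plus its provenance."""

    atoms: struc.AtomArray
    source: str = ""

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.atoms.coord)):
            raise ValueError("structure contains non-finite coordinates")

    @property
    def has_hydrogens(self) -> bool:
        return bool(np.any(self.atoms.element == "H"))

    def chains(self) -> list[str]:
        return sorted(set(self.atoms.chain_id))

    def tryptophan_labels(self) -> list[str]:
        """Chain-qualified labels, e.g. 'A/W106', for every TRP residue."""
        a = self.atoms
        mask = a.res_name == "TRP"
        seen = []
        for ch, ri in zip(a.chain_id[mask], a.res_id[mask]):
            lbl = f"{ch}/W{ri}"
            if lbl not in seen:
                seen.append(lbl)
        return seen

    def residue_mask(self, label: str) -> np.ndarray:
        chain, res = label.split("/")
        res_id = int(res.lstrip("W"))
        a = self.atoms
        mask = (a.chain_id == chain) & (a.res_id == res_id)
        if not np.any(mask):
            raise KeyError(f"residue {label!r} not found in structure")
        return mask

    def atom_position(self, label: str, atom_name: str) -> np.ndarray:
        mask = self.residue_mask(label) & (self.atoms.atom_name == atom_name)
        if not np.any(mask):
            raise KeyError(f"residue {label!r} has no atom {atom_name!r}")
        return self.atoms.coord[mask][0]


@dataclass
class ProtonSet:
    """Positions (Å) of exchangeable protons, with provenance counts."""

    positions: np.ndarray        # (n, 3)
    n_explicit: int
    n_constructed: int

    def __len__(self) -> int:
        return self.positions.shape[0]


@dataclass
class StructureDescriptors:
    """Per-tryptophan descriptor row."""

    label: str
    d_rss: float            # Hz
    sasa: float             # Å^2
    n_protons_used: int
    fluorine_proxy_atom: str = "CZ3"


def read_pdb(path: str | Path) -> StructureModel:
    """Parse a PDB file into a StructureModel (first model only)."""
    path = Path(path)
    try:
        pdb = PDBFile.read(str(path))
        atoms = pdb.get_structure(model=1)
    except Exception as exc:
        bad = _find_malformed_lines(path)
        detail = f"; malformed ATOM/HETATM records at lines {bad}" if bad else ""
        raise ValueError(f"failed to parse {path}: {exc}{detail}") from exc
    return StructureModel(atoms=atoms, source=str(path))


def _find_malformed_lines(path: Path) -> list[int]:
    bad = []
    try:
        for i, line in enumerate(path.read_text().splitlines(), start=1):
            if line.startswith(("ATOM", "HETATM")):
                try:
                    float(line[30:38]); float(line[38:46]); float(line[46:54])
                except (ValueError, IndexError):
                    bad.append(i)
    except OSError:
        pass
    return bad


def select_exchangeable_protons(model: StructureModel) -> ProtonSet:
    """Back-exchangeable proton positions.

    With explicit hydrogens: every H whose nearest heavy atom (within
    1.3 Å) is N, O or S — backbone amides included, aliphatic and aromatic
    C–H excluded.

    Without hydrogens they are constructed: the backbone amide H is placed
    1.01 Å from N along the unit vector C(i−1)→O(i−1) reversed (i.e. trans
    to the preceding carbonyl O, the classic peptide-plane construction);
    side-chain exchangeables are placed 1.0 Å from their heavy atom,
    directed away from the residue's centroid, one placed proton per
    expected hydrogen (protons of an NH₂/NH₃ group share the idealized
    position — a documented simplification).
    """
    a = model.atoms
    if a.array_length() == 0:
        raise ValueError("structure contains no atoms")
    if model.has_hydrogens:
        h_mask = a.element == "H"
        heavy_mask = ~h_mask
        heavy_coord = a.coord[heavy_mask]
        heavy_elem = a.element[heavy_mask]
        positions = []
        for hxyz in a.coord[h_mask]:
            d2 = np.sum((heavy_coord - hxyz) ** 2, axis=1)
            j = int(np.argmin(d2))
            if d2[j] <= 1.3**2 and heavy_elem[j] in ("N", "O", "S"):
                positions.append(hxyz)
        if not positions:
            return ProtonSet(np.empty((0, 3)), 0, 0)
        return ProtonSet(np.array(positions), len(positions), 0)

    positions = []
    # backbone amide H from the peptide-plane geometry
    for chain in model.chains():
        cmask = a.chain_id == chain
        res_ids = sorted(set(a.res_id[cmask]))
        for prev_id, cur_id in zip(res_ids[:-1], res_ids[1:]):
            if cur_id != prev_id + 1:
                continue  # chain break
            cur = cmask & (a.res_id == cur_id)
            if a.res_name[cur][0] == "PRO":
                continue
            try:
                c = a.coord[(cmask & (a.res_id == prev_id) & (a.atom_name == "C"))][0]
                o = a.coord[(cmask & (a.res_id == prev_id) & (a.atom_name == "O"))][0]
                n = a.coord[(cur & (a.atom_name == "N"))][0]
            except IndexError:
                continue
            u = c - o
            norm = np.linalg.norm(u)
            if norm == 0:
                continue
            positions.append(n + 1.01 * u / norm)
    # side-chain exchangeables on their heavy atom + 1.0 A outward offset
    for chain in model.chains():
        cmask = a.chain_id == chain
        for res_id in sorted(set(a.res_id[cmask])):
            rmask = cmask & (a.res_id == res_id)
            res_name = a.res_name[rmask][0]
            sites = _SIDECHAIN_EXCHANGEABLE.get(res_name)
            if not sites:
                continue
            centroid = a.coord[rmask].mean(axis=0)
            for atom_name, n_h in sites.items():
                sel = rmask & (a.atom_name == atom_name)
                if not np.any(sel):
                    continue
                heavy = a.coord[sel][0]
                u = heavy - centroid
                norm = np.linalg.norm(u)
                u = u / norm if norm > 0 else np.array([0.0, 0.0, 1.0])
                site = heavy + 1.0 * u
                positions.extend([site] * n_h)
    if not positions:
        return ProtonSet(np.empty((0, 3)), 0, 0)
    arr = np.array(positions)
    return ProtonSet(arr, 0, arr.shape[0])


def dipolar_coupling(gamma_a: float, gamma_b: float, r: float) -> float:
    """Magnitude of the dipolar coupling constant in Hz.

    d = (μ₀/4π) γ_a γ_b ħ / (2π r³), with gyromagnetic ratios in
    rad s⁻¹ T⁻¹ and ``r`` in Å.
    """
    if r <= 0:
        raise ValueError(f"r must be positive, got {r}")
    c = CONSTANTS
    r_m = r * ANGSTROM
    return (c.mu0 / (4.0 * math.pi)) * abs(gamma_a * gamma_b) * c.hbar / (
        2.0 * math.pi * r_m**3
    )


def d_rss(
    model: StructureModel,
    trp_label: str,
    proxy_atom: str = "CZ3",
    protons: ProtonSet | None = None,
) -> tuple[float, int]:
    """Root-sum-square ¹⁹F–¹H dipolar coupling for one tryptophan (Hz).

    The fluorine position is the residue's ``proxy_atom`` (CZ3, the
    5-position carbon); the proton set spans the full model — all chains
    of the assembly — unless one is passed in.  Returns (d_rss, n_protons).
    """
    fpos = model.atom_position(trp_label, proxy_atom)
    if protons is None:
        protons = select_exchangeable_protons(model)
    if len(protons) == 0:
        return 0.0, 0
    dists = np.linalg.norm(protons.positions - fpos, axis=1)
    dists = dists[dists > 1e-6]  # guard against a proton on the proxy site
    gf = CONSTANTS.gamma_of("19F")
    gh = CONSTANTS.gamma_of("1H")
    couplings = np.array([dipolar_coupling(gf, gh, r) for r in dists])
    return float(np.sqrt(np.sum(couplings**2))), int(dists.size)


def _radii_for(atoms: struc.AtomArray) -> np.ndarray:
    radii = np.empty(atoms.array_length())
    for i, el in enumerate(atoms.element):
        try:
            radii[i] = VDW_RADII[el]
        except KeyError:
            raise KeyError(f"no van-der-Waals radius for element {el!r}") from None
    return radii


def sasa(atoms: struc.AtomArray) -> np.ndarray:
    """Per-atom solvent-accessible surface area (Å²).

    Sphere-point (Shrake–Rupley-style) integration with a 1.4 Å probe,
    960 points per atom and the standard van-der-Waals radius set
    (H 1.2, C 1.7, N 1.55, O 1.52, S 1.8 Å).
    """
    return struc.sasa(
        atoms,
        probe_radius=PROBE_RADIUS,
        point_number=SASA_POINTS,
        vdw_radii=_radii_for(atoms),
        ignore_ions=False,
    )


def residue_sasa(model: StructureModel, label: str) -> float:
    """SASA of one residue (Å²) computed in the context of the full assembly."""
    per_atom = sasa(model.atoms)
    mask = model.residue_mask(label)
    return float(np.nansum(per_atom[mask]))


def compute_descriptors(
    model: StructureModel, proxy_atom: str = "CZ3"
) -> list[StructureDescriptors]:
    """d_rss and SASA for every tryptophan in the model."""
    protons = select_exchangeable_protons(model)
    per_atom = sasa(model.atoms)
    rows = []
    for label in model.tryptophan_labels():
        val, n_used = d_rss(model, label, proxy_atom=proxy_atom, protons=protons)
        rows.append(
            StructureDescriptors(
                label=label,
                d_rss=val,
                sasa=float(np.nansum(per_atom[model.residue_mask(label)])),
                n_protons_used=n_used,
                fluorine_proxy_atom=proxy_atom,
            )
        )
    return rows


def correlate_descriptors(
    descriptor: Mapping[str, float],
    gamma: Mapping[str, float],
    max_exact: int = 7,
    n_random: int = 10000,
    seed: int | None = 0,
) -> dict[str, float]:
    """Pearson correlation between a descriptor and measured Γ values.

    The two-sided p-value comes from the permutation null: for n ≤
    ``max_exact`` all n! label permutations are enumerated (24 for the
    four tryptophans), otherwise a seeded random sample is used.  The
    p-value is the fraction of permutations with |r| ≥ |r_observed|.
    """
    labels = sorted(set(descriptor) & set(gamma))
    if len(labels) < 3:
        raise ValueError(f"need at least 3 residues with both values, got {len(labels)}")
    x = np.array([descriptor[l] for l in labels])
    y = np.array([gamma[l] for l in labels])
    r_obs = float(np.corrcoef(x, y)[0, 1])
    n = len(labels)
    if n <= max_exact:
        perms = list(itertools.permutations(range(n)))
    else:
        rng = np.random.default_rng(seed)
        perms = [rng.permutation(n) for _ in range(n_random)]
    r_null = np.array([np.corrcoef(x, y[list(p)])[0, 1] for p in perms])
    p_val = float(np.mean(np.abs(r_null) >= abs(r_obs) - 1e-12))
    return {"r": r_obs, "p": p_val, "n": n, "n_permutations": len(perms)}
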