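"""Synthetic inputs with known ground truth for every pipeline stage.

Coordinate builders lay down poly-alanine backbones atom by atom from
idealised bond lengths and angles at exact target torsions, so detected
H-bonds, torsions and secondary structure can be checked against the
construction. Curve and table builders emit the pipeline's own text
formats. All builders are deterministic: the same parameters and seed
give byte-identical output.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import least_squares

from .constants import (ANGLE_C_N_CA, ANGLE_CA_C_N, ANGLE_CA_C_O,
                        ANGLE_N_CA_C, ANGLE_N_CA_CB, BOND_C_N, BOND_C_O,
                        BOND_CA_C, BOND_CA_CB, BOND_N_CA, OMEGA_TRANS)
from .geometry import place_atom
from .melting import BaselineModel, MeltingCurve, two_state_signal


class FixtureError(ValueError):
    """Raised for invalid fixture parameters."""


def _build_backbone(torsions: list[tuple[float, float]],
                    origin=np.zeros(3)) -> list[dict[str, np.ndarray]]:
    """Backbone atoms (N, CA, C, O, CB) for each residue at given (phi, psi).

    phi of the first residue and psi of the last are unused (undefined).
    Omega is held at 180 degrees (trans).
    """
    n = len(torsions)
    res: list[dict[str, np.ndarray]] = [dict() for _ in range(n)]
    # Seed the first three atoms in a canonical frame.
    res[0]["N"] = origin + np.array([0.0, 0.0, 0.0])
    res[0]["CA"] = origin + np.array([BOND_N_CA, 0.0, 0.0])
    theta = np.radians(180.0 - ANGLE_N_CA_C)
    res[0]["C"] = res[0]["CA"] + BOND_CA_C * np.array(
        [np.cos(theta), np.sin(theta), 0.0])
    for i in range(n):
        phi, psi = torsions[i]
        if i > 0:
            prev = res[i - 1]
            res[i]["N"] = place_atom(prev["N"], prev["CA"], prev["C"],
                                     BOND_C_N, ANGLE_CA_C_N, torsions[i - 1][1])
            res[i]["CA"] = place_atom(prev["CA"], prev["C"], res[i]["N"],
                                      BOND_N_CA, ANGLE_C_N_CA, OMEGA_TRANS)
            res[i]["C"] = place_atom(prev["C"], res[i]["N"], res[i]["CA"],
                                     BOND_CA_C, ANGLE_N_CA_C, phi)
        # Carbonyl oxygen: anti to the next amide nitrogen (psi + 180).
        res[i]["O"] = place_atom(res[i]["N"], res[i]["CA"], res[i]["C"],
                                 BOND_C_O, ANGLE_CA_C_O, psi + 180.0)
        # C-beta off the N-CA-C frame (tetrahedral branch).
        res[i]["CB"] = place_atom(res[i]["C"], res[i]["N"], res[i]["CA"],
                                  BOND_CA_CB, ANGLE_N_CA_CB, 122.5)
    return res


def _to_pdb(residues: list[dict[str, np.ndarray]], chain_id: str = "A",
            start: int = 1, res_name: str = "ALA") -> str:
    lines = []
    serial = 1
    for i, atoms in enumerate(residues):
        for name in ("N", "CA", "C", "O", "CB"):
            if name not in atoms:
                continue
            x, y, z = atoms[name]
            lines.append(
                f"ATOM  {serial:5d}  {name:<3s}{res_name:>4s} {chain_id}"
                f"{start + i:4d}    {x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00"
                f"          {name[0]:>2s}")
            serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


def build_ideal_helix(n_residues: int, phi: float = -57.0,
                      psi: float = -47.0, chain_id: str = "A",
                      start: int = 1) -> str:
    """PDB text of an ideal poly-alanine helix at exact (phi, psi).

    At the alpha-helical defaults every i -> i+4 amide-to-carbonyl pair
    satisfies the H-bond criteria (N...O well under 3.28 A).
    """
    if n_residues < 6:
        raise FixtureError("an ideal helix fixture needs at least 6 residues")
    residues = _build_backbone([(phi, psi)] * n_residues)
    return _to_pdb(residues, chain_id, start)


def build_extended_chain(n_residues: int, chain_id: str = "A") -> str:
    """Fully extended chain (phi = psi = 180): no N...O pair within 3.28 A."""
    if n_residues < 2:
        raise FixtureError("need at least 2 residues")
    residues = _build_backbone([(180.0, 180.0)] * n_residues)
    return _to_pdb(residues, chain_id)


def build_ideal_hairpin(n_per_strand: int = 6,
                        phi: float = -139.0, psi: float = 135.0) -> str:
    """Two-chain antiparallel beta pair at exact strand torsions.

    Strand A is built at (phi, psi); strand B is an identical strand,
    rigidly placed (deterministic local optimisation, fixed start) so that
    the antiparallel ladder rungs N_i...O_j / N_j...O_i fall at canonical
    H-bond distances. Chains A and B carry the register i <-> j pairing
    with j running antiparallel to i.
    """
    if n_per_strand < 4:
        raise FixtureError("need at least 4 residues per strand")
    torsions = [(phi, psi)] * n_per_strand
    strand_a = _build_backbone(torsions)
    strand_b0 = _build_backbone(torsions)

    def transform(params: np.ndarray, atoms_list):
        rx, ry, rz, tx, ty, tz = params
        from scipy.spatial.transform import Rotation
        rot = Rotation.from_euler("xyz", [rx, ry, rz]).as_matrix()
        t = np.array([tx, ty, tz])
        return [{k: rot @ v + t for k, v in atoms.items()}
                for atoms in atoms_list]

    # Antiparallel register: residue i of A pairs with residue
    # j = n-1-i of B. H-bonded rungs alternate; target the even i.
    rungs = [(i, n_per_strand - 1 - i) for i in range(0, n_per_strand, 2)
             if 0 < n_per_strand - 1 - i < n_per_strand]

    def objective(params: np.ndarray) -> np.ndarray:
        b = transform(params, strand_b0)
        resid = []
        for i, j in rungs:
            resid.append(np.linalg.norm(strand_a[i]["N"] - b[j]["O"]) - 2.95)
            resid.append(np.linalg.norm(b[j]["N"] - strand_a[i]["O"]) - 2.95)
        # keep CA-CA across the rungs near sheet spacing to fix orientation
        for i, j in rungs:
            resid.append(
                (np.linalg.norm(strand_a[i]["CA"] - b[j]["CA"]) - 4.9) * 0.3)
        return np.asarray(resid)

    x0 = np.array([np.pi, 0.0, 0.0, 0.0, 4.8, 0.0])
    sol = least_squares(objective, x0, method="lm", max_nfev=20000)
    strand_b = transform(sol.x, strand_b0)
    return (_to_pdb(strand_a, "A", 1).replace("END\n", "")
            + _to_pdb(strand_b, "B", 101))


def build_two_island(separation: float = 20.0, residues_per_island: int = 8,
                     seed: int = 0) -> tuple[str, str, dict[str, set[int]]]:
    """Two helical islands with a planted free-energy split.

    Returns (pdb_text, exchange_table_text, truth) where truth maps island
    label ('island_1', 'island_2') to author residue numbers. Island 1
    carries dG_HX drawn from 4.0-6.0 kcal/mol, island 2 from 1.5-3.5, so
    cluster recovery can be checked against the construction. Centroids of
    the two islands sit ``separation`` angstroms apart, perpendicular to
    the helix axes.
    """
    if separation <= 0:
        raise FixtureError("separation must be positive")
    rng = np.random.default_rng(seed)
    helix_a = _build_backbone([(-57.0, -47.0)] * residues_per_island)
    helix_b = _build_backbone([(-57.0, -47.0)] * residues_per_island)
    centroid = np.mean([a["CA"] for a in helix_a], axis=0)
    axis = helix_a[-1]["CA"] - helix_a[0]["CA"]
    axis /= np.linalg.norm(axis)
    # displacement perpendicular to the helix axis
    perp = np.cross(axis, [0.0, 0.0, 1.0])
    if np.linalg.norm(perp) < 1e-6:
        perp = np.cross(axis, [0.0, 1.0, 0.0])
    perp /= np.linalg.norm(perp)
    shift = perp * separation
    helix_b = [{k: v + shift for k, v in atoms.items()} for atoms in helix_b]

    pdb_text = (_to_pdb(helix_a, "A", 1).replace("END\n", "")
                + _to_pdb(helix_b, "A", 101))
    numbers_a = list(range(1, residues_per_island + 1))
    numbers_b = list(range(101, 101 + residues_per_island))
    rows = ["# residue\tchain\tdG_hx"]
    for num in numbers_a:
        rows.append(f"{num}\tA\t{rng.uniform(4.0, 6.0):.3f}")
    for num in numbers_b:
        rows.append(f"{num}\tA\t{rng.uniform(1.5, 3.5):.3f}")
    truth = {"island_1": set(numbers_a), "island_2": set(numbers_b)}
    return pdb_text, "\n".join(rows) + "\n", truth


def build_melting_curve(dg_u: float, m: float,
                        pre: BaselineModel | None = None,
                        post: BaselineModel | None = None,
                        noise_sd: float = 0.0, seed: int = 0,
                        n_points: int = 40, c_max: float = 6.0,
                        T: float = 288.0) -> MeltingCurve:
    """Synthetic denaturation curve from the two-state model plus noise.

    Emulates a well-designed melt: half the points uniform over
    [0, c_max], half concentrated within +/- 1 M of the midpoint, the way
    an experimentalist resolves the transition. ``noise_sd`` is the
    Gaussian standard deviation in signal units (use 0.01 * signal span
    for "1% noise"). Deterministic under a fixed seed.
    """
    pre = pre or BaselineModel("linear", (1.0, -0.02))
    post = post or BaselineModel("linear", (0.05, 0.01))
    rng = np.random.default_rng(seed)
    cm = dg_u / m
    C = np.sort(np.concatenate([
        np.linspace(0.0, c_max, n_points // 2),
        np.linspace(max(cm - 1.0, 0.0), min(cm + 1.0, c_max),
                    n_points - n_points // 2),
    ]))
    S = two_state_signal(C, dg_u, m, pre, post, T)
    if noise_sd > 0:
        S = S + rng.normal(0.0, noise_sd, size=S.shape)
    return MeltingCurve(C, S)


def melting_curve_text(curve: MeltingCurve) -> str:
    """Serialize a curve in the pipeline's two-column TSV format."""
    rows = ["# concentration_M\tsignal"]
    for c, s in zip(curve.concentrations, curve.signals):
        rows.append(f"{c:.6f}\t{s:.6f}")
    return "\n".join(rows) + "\n"


def build_exchange_table(dg_values: dict[int, float], chain_id: str = "A",
                         as_rates: bool = False, k_rc: float | None = None,
                         T: float = 298.0) -> str:
    """Exchange-table TSV from residue-number -> dG_HX values.

    With ``as_rates=True`` the table carries k_ex back-computed from a
    common k_rc instead (for round-trip tests).
    """
    if as_rates:
        if k_rc is None:
            raise FixtureError("as_rates requires a k_rc")
        from .constants import R_KCAL
        rows = ["# residue\tchain\tk_ex"]
        for num, dg in sorted(dg_values.items()):
            k_ex = k_rc * np.exp(-dg / (R_KCAL * T))
            rows.append(f"{num}\t{chain_id}\t{k_ex:.8e}")
    else:
        rows = ["# residue\tchain\tdG_hx"]
        for num, dg in sorted(dg_values.items()):
            rows.append(f"{num}\t{chain_id}\t{dg:.4f}")
    return "\n".join(rows) + "\n"
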