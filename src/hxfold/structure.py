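"""Structural model: PDB parsing and all geometry the pipeline consumes.

Every downstream stage works from this module's view of a structure:
disulfide detection (S-S pairs within 2.3 A), Xaa-Pro cis/trans calls from
the Calpha-Calpha vs Calpha-Cdelta distance criterion, backbone H-bonds under
the Stickle-style heavy-atom criteria (N...O <= 3.28 A, both the N-O=C and
O-N-Calpha angles in [90, 180] degrees), secondary-structure labels from
H-bond patterns plus torsion windows, and backbone-nitrogen distances.

Residues are keyed by author (PDB) numbering with chain id; no renumbering
is ever applied, so cluster reports can be read against published tables.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionException

from .constants import (
    AA_3TO1,
    DISULFIDE_CUTOFF,
    HBOND_ANGLE_MAX,
    HBOND_ANGLE_MIN,
    HBOND_DISTANCE_CUTOFF,
    TORSION_WINDOWS,
)
from .geometry import angle, dihedral, distance


class StructureError(ValueError):
    """Raised for unusable or malformed structural input."""


ResidueKey = tuple[str, int, str]  # (chain id, author number, insertion code)


@dataclass
class Residue:
    """One amino-acid residue: author identity plus atom coordinates (A)."""

    chain_id: str
    number: int
    icode: str
    name: str
    atoms: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def key(self) -> ResidueKey:
        return (self.chain_id, self.number, self.icode)

    @property
    def one_letter(self) -> str:
        return AA_3TO1.get(self.name, "X")

    def has(self, *atom_names: str) -> bool:
        return all(a in self.atoms for a in atom_names)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"<Residue {self.chain_id}:{self.name}{self.number}{self.icode.strip()}>"


@dataclass
class ProteinStructure:
    """Parsed structure: ordered residues of the first model, standard
    amino acids only, alternate locations resolved to ' '/'A'."""

    id: str
    residues: list[Residue]

    def __post_init__(self) -> None:
        self._index = {r.key: r for r in self.residues}
        if len(self._index) != len(self.residues):
            raise StructureError("duplicate residue identifiers in structure")
        if not any(r.has("N") for r in self.residues):
            raise StructureError("no residue with a backbone nitrogen atom")
        for r in self.residues:
            for name, xyz in r.atoms.items():
                if not np.all(np.isfinite(xyz)):
                    raise StructureError(f"non-finite coordinates for {r!r} atom {name}")

    def __len__(self) -> int:
        return len(self.residues)

    def get(self, key: ResidueKey) -> Residue:
        return self._index[key]

    def chain(self, chain_id: str) -> list[Residue]:
        return [r for r in self.residues if r.chain_id == chain_id]

    def chain_ids(self) -> list[str]:
        seen: list[str] = []
        for r in self.residues:
            if r.chain_id not in seen:
                seen.append(r.chain_id)
        return seen

    def sequence(self, chain_id: str | None = None) -> str:
        res = self.residues if chain_id is None else self.chain(chain_id)
        return "".join(r.one_letter for r in res)


@dataclass
class DisulfideAssignment:
    """S-S pairing of cysteines: bonded pairs with distances, free cysteines
    with their nearest SG-SG distance (None when the protein has one Cys)."""

    pairs: list[tuple[ResidueKey, ResidueKey, float]]
    free_cysteines: list[tuple[ResidueKey, float | None]]

    def is_cystine(self, key: ResidueKey) -> bool:
        return any(key in (a, b) for a, b, _ in self.pairs)


@dataclass
class ProlineAssignment:
    """Conformation of one Xaa-Pro peptide bond from the distance criterion:
    trans iff d(Calpha_Xaa, Calpha_Pro) > d(Calpha_Xaa, Cdelta_Pro)."""

    residue: ResidueKey
    preceding: ResidueKey
    preceding_name: str
    d_ca_ca: float
    d_ca_cd: float
    conformation: str  # "cis" | "trans"


@dataclass(frozen=True)
class HydrogenBond:
    """Backbone amide H-bond described by heavy atoms only."""

    donor: ResidueKey       # residue whose N-H donates
    acceptor: ResidueKey    # residue whose C=O accepts
    distance: float         # N...O, angstrom
    acceptor_angle: float   # N-O=C at the acceptor oxygen, degrees
    donor_angle: float      # O-N-Calpha at the donor nitrogen, degrees


@dataclass
class SecondaryStructureAssignment:
    """Per-residue secondary-structure labels and backbone torsions."""

    labels: dict[ResidueKey, str]
    torsions: dict[ResidueKey, tuple[float | None, float | None]]

    def label(self, key: ResidueKey) -> str:
        return self.labels.get(key, "none")


_WATER_NAMES = {"HOH", "WAT", "DOD"}


def parse_pdb(pdb_text: str, structure_id: str = "structure") -> ProteinStructure:
    """Parse PDB-format text into a :class:`ProteinStructure`.

    First MODEL only; HETATM records and waters are ignored; alternate
    locations other than ' '/'A' are dropped; hydrogens are retained but
    unused by the geometry routines.
    """
    if "ATOM" not in pdb_text:
        raise StructureError("input contains no ATOM records")
    _validate_atom_lines(pdb_text)
    parser = PDBParser(PERMISSIVE=True, QUIET=True)
    try:
        bio = parser.get_structure(structure_id, io.StringIO(pdb_text))
    except PDBConstructionException as exc:  # pragma: no cover - defensive
        raise StructureError(f"PDB parse failure: {exc}") from exc
    models = list(bio.get_models())
    if not models:
        raise StructureError("no coordinate model found")
    model = models[0]

    residues: list[Residue] = []
    for chain in model:
        for res in chain:
            hetflag, resseq, icode = res.get_id()
            if hetflag != " ":
                continue
            name = res.get_resname().strip()
            if name in _WATER_NAMES or name not in AA_3TO1:
                continue
            atoms: dict[str, np.ndarray] = {}
            for atom in res:
                altloc = atom.get_altloc()
                if altloc not in (" ", "A"):
                    continue
                if atom.get_name() in atoms:
                    continue
                atoms[atom.get_name()] = np.asarray(atom.get_coord(), dtype=float)
            if atoms:
                residues.append(Residue(chain.id, resseq, icode, name, atoms))
    if not residues:
        raise StructureError("no standard amino-acid residues parsed")
    return ProteinStructure(structure_id, residues)


def _validate_atom_lines(pdb_text: str) -> None:
    """Fail early, naming the offending line, on malformed coordinates."""
    for lineno, line in enumerate(pdb_text.splitlines(), start=1):
        if not line.startswith(("ATOM  ", "HETATM")):
            continue
        if len(line) < 54:
            raise StructureError(f"line {lineno}: truncated ATOM record")
        for lo, hi, label in ((30, 38, "x"), (38, 46, "y"), (46, 54, "z")):
            fieldtxt = line[lo:hi].strip()
            try:
                float(fieldtxt)
            except ValueError:
                raise StructureError(
                    f"line {lineno}: malformed {label} coordinate field {fieldtxt!r}"
                ) from None


def detect_disulfides(s: ProteinStructure,
                      cutoff: float = DISULFIDE_CUTOFF) -> DisulfideAssignment:
    """Greedy nearest-pair matching of cysteine SG atoms under the cutoff.

    Two cysteines are a cystine when their sulphur atoms are within
    ``cutoff`` (inclusive). Cysteines lacking an SG atom are excluded with
    a warning.
    """
    cys = []
    for r in s.residues:
        if r.name != "CYS":
            continue
        if not r.has("SG"):
            warnings.warn(f"cysteine {r!r} lacks an SG atom; excluded from "
                          "disulfide detection")
            continue
        cys.append(r)

    candidates = []
    for i in range(len(cys)):
        for j in range(i + 1, len(cys)):
            d = distance(cys[i].atoms["SG"], cys[j].atoms["SG"])
            candidates.append((d, cys[i].key, cys[j].key))
    candidates.sort(key=lambda t: (t[0], t[1], t[2]))

    paired: set[ResidueKey] = set()
    pairs: list[tuple[ResidueKey, ResidueKey, float]] = []
    for d, a, b in candidates:
        if d > cutoff:
            break
        if a in paired or b in paired:
            continue
        pairs.append((a, b, round(d, 3)))
        paired.update((a, b))

    free: list[tuple[ResidueKey, float | None]] = []
    for r in cys:
        if r.key in paired:
            continue
        others = [distance(r.atoms["SG"], o.atoms["SG"])
                  for o in cys if o.key != r.key]
        free.append((r.key, round(min(others), 3) if others else None))
    return DisulfideAssignment(pairs, free)


def classify_prolines(s: ProteinStructure) -> list[ProlineAssignment]:
    """Call cis/trans for every Xaa-Pro peptide bond.

    trans iff d(Calpha_Xaa, Calpha_Pro) > d(Calpha_Xaa, Cdelta_Pro);
    cis otherwise. An N-terminal proline (no preceding residue in its
    chain) is skipped with a warning; a proline missing its Cdelta is an
    error naming the residue.
    """
    out: list[ProlineAssignment] = []
    for chain_id in s.chain_ids():
        chain = s.chain(chain_id)
        for idx, r in enumerate(chain):
            if r.name != "PRO":
                continue
            if idx == 0:
                warnings.warn(f"N-terminal proline {r!r} has no preceding "
                              "residue; skipped")
                continue
            prev = chain[idx - 1]
            if not r.has("CD"):
                raise StructureError(f"proline {r!r} lacks a CD atom")
            if not r.has("CA") or not prev.has("CA"):
                raise StructureError(f"missing CA atom around proline {r!r}")
            d_ca_ca = distance(prev.atoms["CA"], r.atoms["CA"])
            d_ca_cd = distance(prev.atoms["CA"], r.atoms["CD"])
            conformation = "trans" if d_ca_ca > d_ca_cd else "cis"
            out.append(ProlineAssignment(r.key, prev.key, prev.name,
                                         round(d_ca_ca, 3), round(d_ca_cd, 3),
                                         conformation))
    return out


def detect_backbone_hbonds(s: ProteinStructure,
                           distance_cutoff: float = HBOND_DISTANCE_CUTOFF,
                           ) -> list[HydrogenBond]:
    """All backbone N-H...O=C hydrogen bonds under the heavy-atom criteria.

    A donor is any backbone N except proline and each chain's first residue;
    an acceptor is any backbone carbonyl. Criteria (all inclusive):
    N...O <= 3.28 A, the N-O=C angle at the acceptor oxygen and the
    O-N-Calpha angle at the donor nitrogen both in [90, 180] degrees, and
    sequence separation of at least two positions. When several acceptors
    qualify for one donor, the shortest N...O is kept (single amide proton).
    """
    donors: list[tuple[int, Residue]] = []
    acceptors: list[tuple[int, Residue]] = []
    order = {r.key: i for i, r in enumerate(s.residues)}
    first_of_chain = {chain_id: s.chain(chain_id)[0].key for chain_id in s.chain_ids()}
    for r in s.residues:
        if r.name != "PRO" and r.key != first_of_chain[r.chain_id] \
                and r.has("N", "CA"):
            donors.append((order[r.key], r))
        if r.has("C", "O"):
            acceptors.append((order[r.key], r))

    bonds: list[HydrogenBond] = []
    for di, dres in donors:
        best: HydrogenBond | None = None
        n_xyz, ca_xyz = dres.atoms["N"], dres.atoms["CA"]
        for ai, ares in acceptors:
            if dres.chain_id == ares.chain_id and abs(di - ai) < 2:
                continue
            o_xyz, c_xyz = ares.atoms["O"], ares.atoms["C"]
            d = distance(n_xyz, o_xyz)
            if d > distance_cutoff:
                continue
            acc_angle = angle(n_xyz, o_xyz, c_xyz)
            don_angle = angle(o_xyz, n_xyz, ca_xyz)
            if not (HBOND_ANGLE_MIN <= acc_angle <= HBOND_ANGLE_MAX):
                continue
            if not (HBOND_ANGLE_MIN <= don_angle <= HBOND_ANGLE_MAX):
                continue
            hb = HydrogenBond(dres.key, ares.key, d, acc_angle, don_angle)
            if best is None or hb.distance < best.distance:
                best = hb
        if best is not None:
            bonds.append(best)
    return bonds


def backbone_torsions(s: ProteinStructure) -> dict[ResidueKey,
                                                   tuple[float | None, float | None]]:
    """(phi, psi) per residue; None where the flanking atoms are absent."""
    torsions: dict[ResidueKey, tuple[float | None, float | None]] = {}
    for chain_id in s.chain_ids():
        chain = s.chain(chain_id)
        for i, r in enumerate(chain):
            phi = psi = None
            if r.has("N", "CA", "C"):
                if i > 0 and chain[i - 1].has("C"):
                    phi = dihedral(chain[i - 1].atoms["C"], r.atoms["N"],
                                   r.atoms["CA"], r.atoms["C"])
                if i + 1 < len(chain) and chain[i + 1].has("N"):
                    psi = dihedral(r.atoms["N"], r.atoms["CA"],
                                   r.atoms["C"], chain[i + 1].atoms["N"])
            torsions[r.key] = (phi, psi)
    return torsions


def _in_window(value: float | None, center: float, half_width: float) -> bool:
    if value is None:
        return False
    delta = (value - center + 180.0) % 360.0 - 180.0
    return abs(delta) <= half_width


def _torsion_ok(key: ResidueKey, label: str,
                torsions: dict[ResidueKey, tuple[float | None, float | None]]) -> bool:
    phi_c, psi_c, hw = TORSION_WINDOWS[label]
    phi, psi = torsions.get(key, (None, None))
    return _in_window(phi, phi_c, hw) and _in_window(psi, psi_c, hw)


def assign_secondary_structure(s: ProteinStructure,
                               hbonds: list[HydrogenBond],
                               min_run: int = 2) -> SecondaryStructureAssignment:
    """Label residues by H-bond pattern plus torsion window.

    Helices (alpha: i -> i+4 bonds; 3-10: i -> i+3) require a run of at
    least ``min_run`` consecutive bonds of the class. Sheets require a
    ladder of at least ``min_run`` registered rungs: antiparallel rung
    (i, j) means N_i -> O_j and N_j -> O_i; parallel rung means
    N_i -> O_(j-1) and N_(j+1) -> O_i; consecutive rungs step by two
    positions along each strand. A residue in a qualifying pattern is
    labelled only if its (phi, psi) fall inside the class window.
    Precedence when patterns overlap: alpha helix, 3-10 helix,
    antiparallel sheet, parallel sheet.
    """
    torsions = backbone_torsions(s)
    order = {r.key: i for i, r in enumerate(s.residues)}
    keys = [r.key for r in s.residues]
    same_chain = lambda i, j: s.residues[i].chain_id == s.residues[j].chain_id

    donor_to_acceptor: dict[int, set[int]] = {}
    for hb in hbonds:
        donor_to_acceptor.setdefault(order[hb.donor], set()).add(order[hb.acceptor])

    def has_bond(i: int, j: int) -> bool:
        """Donor i -> acceptor j."""
        return (0 <= i < len(keys) and 0 <= j < len(keys)
                and j in donor_to_acceptor.get(i, ()))

    candidates: dict[str, set[int]] = {k: set() for k in TORSION_WINDOWS}

    # Helical patterns: anchors i with bond N_(i+offset) -> O_i within one chain.
    for label, offset in (("alpha_helix", 4), ("three_ten_helix", 3)):
        anchors = sorted(i for i in range(len(keys) - offset)
                         if has_bond(i + offset, i) and same_chain(i, i + offset))
        run: list[int] = []
        for i in anchors + [None]:  # type: ignore[list-item]
            if run and (i is None or i != run[-1] + 1):
                if len(run) >= min_run:
                    for j in range(run[0], run[-1] + offset + 1):
                        candidates[label].add(j)
                run = []
            if i is not None:
                run.append(i)

    # Sheet ladders.
    anti_rungs = set()
    para_rungs = set()
    for i in range(len(keys)):
        for j in donor_to_acceptor.get(i, ()):
            if has_bond(j, i) and i < j:
                anti_rungs.add((i, j))
            if has_bond(j + 2, i) and same_chain(i, j):
                # N_i -> O_(j'), with j' = j; rung (i, j+1) under the
                # parallel register N_i -> O_(j'-1), N_(j'+1) -> O_i.
                para_rungs.add((i, j + 1))
    for rungs, label, step in ((anti_rungs, "antiparallel_beta", -2),
                               (para_rungs, "parallel_beta", 2)):
        for (i, j) in rungs:
            nxt = (i + 2, j + step)
            if nxt in rungs:
                for a in range(i, i + 3):
                    candidates[label].add(a)
                lo, hi = sorted((j, j + step))
                for b in range(lo, hi + 1):
                    candidates[label].add(b)

    labels: dict[ResidueKey, str] = {}
    for idx, key in enumerate(keys):
        assigned = "none"
        for label in ("alpha_helix", "three_ten_helix",
                      "antiparallel_beta", "parallel_beta"):
            if idx in candidates[label] and _torsion_ok(key, label, torsions):
                assigned = label
                break
        labels[key] = assigned
    return SecondaryStructureAssignment(labels, torsions)


def backbone_N_distance(s: ProteinStructure, res_a: ResidueKey,
                        res_b: ResidueKey) -> float:
    """Distance between the backbone nitrogen atoms of two residues, A."""
    a, b = s.get(res_a), s.get(res_b)
    for r in (a, b):
        if not r.has("N"):
            raise StructureError(f"residue {r!r} lacks a backbone N atom")
    return distance(a.atoms["N"], b.atoms["N"])


def write_pdb(s: ProteinStructure, residue_keys: list[ResidueKey] | None = None,
              title: str | None = None) -> str:
    """Serialize (a subset of) the structure as standard PDB text."""
    keys = set(residue_keys) if residue_keys is not None else None
    lines = []
    if title:
        lines.append(f"REMARK   1 {title}")
    serial = 1
    for r in s.residues:
        if keys is not None and r.key not in keys:
            continue
        for atom_name, xyz in r.atoms.items():
            name_field = atom_name if len(atom_name) == 4 else f" {atom_name:<3s}"
            element = atom_name.strip()[0]
            lines.append(
                f"ATOM  {serial:5d} {name_field:<4s} {r.name:>3s} {r.chain_id}"
                f"{r.number:4d}{r.icode:1s}   "
                f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.0:6.2f}{0.0:6.2f}"
                f"          {element:>2s}"
            )
            serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"
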