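"""Toy solvation-trajectory generator with a known hydrogen-bond schedule.

Stands in for long explicit-solvent MD runs: a thiol-like (one S with a
bonded H, as in GSH) or disulfide-like (two S, no S-bonded H, as in GSSG)
solute is fixed at the center of an orthorhombic water box, and water
molecules are *placed*, frame by frame, so that a prescribed
:class:`BondSchedule` is realized geometrically — during its interval a
scheduled water satisfies the geometric hydrogen-bond criteria for its
direction (O-H...S or S-H...O), and outside it the water sits in bulk, at
least 6 A from sulfur, violating the distance criterion with a wide margin.

There is no integrator, thermostat or force field: waters are re-placed
independently every frame.  The artifact exists to give the hydration
analysis exact, enumerable ground truth for bookkeeping (intervals,
residence times, scores), not to produce physical dynamics.

Formats: multi-frame XYZ for coordinates, a JSON sidecar for the topology
(roles + bonds + box), CSV for the schedule.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ROLES = ("sulfur", "sulfur_hydrogen", "water_oxygen", "water_hydrogen", "other")

_OH = 0.9572        # water O-H bond length, A
_HOH = np.deg2rad(104.52)
_SH = 1.34          # thiol S-H bond length, A
_SS = 2.05          # disulfide S-S bond length, A


@dataclass
class Topology:
    """Per-atom roles and bonding needed for directional H-bond analysis."""

    elements: list
    roles: list                       # one of ROLES per atom
    molecule_ids: list
    bonds: dict                       # hydrogen index -> bonded heavy-atom index

    def __post_init__(self):
        bad = [r for r in self.roles if r not in ROLES]
        if bad:
            raise ValueError(f"unknown roles: {sorted(set(bad))}")
        for h, heavy in self.bonds.items():
            hr, ar = self.roles[h], self.roles[heavy]
            if hr == "water_hydrogen" and ar != "water_oxygen":
                raise ValueError(f"water hydrogen {h} bonded to non-oxygen {heavy}")
            if hr == "sulfur_hydrogen" and ar != "sulfur":
                raise ValueError(f"sulfur hydrogen {h} bonded to non-sulfur {heavy}")

    def atoms_with_role(self, role: str) -> np.ndarray:
        return np.array([i for i, r in enumerate(self.roles) if r == role], dtype=int)

    @property
    def n_atoms(self) -> int:
        return len(self.roles)


@dataclass
class Trajectory:
    box: np.ndarray                   # (3,) orthorhombic box lengths, A
    frames: np.ndarray                # (n_frames, n_atoms, 3), A
    topology: Topology
    frame_spacing_ps: float = 10.0    # metadata only, never used in scoring

    def __post_init__(self):
        self.box = np.asarray(self.box, dtype=float)
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must have shape (n_frames, n_atoms, 3)")
        if self.frames.shape[1] != self.topology.n_atoms:
            raise ValueError("frame atom count disagrees with topology")
        if np.any(self.box <= 0):
            raise ValueError("box lengths must be positive")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("non-finite coordinates")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


@dataclass
class BondSchedule:
    """Ground-truth directed H-bond intervals the generator realizes.

    Each row: (donor_hydrogen_id, acceptor_id, start_frame, end_frame)
    with the frame range inclusive.  The donor hydrogen identifies the
    direction: a water hydrogen donating to S is O-H...S; the sulfur
    hydrogen donating to a water oxygen is S-H...O.
    """

    intervals: list = field(default_factory=list)  # (h_id, acc_id, start, end)

    def validate(self, n_frames: int) -> None:
        seen: dict = {}
        for h, a, s, e in self.intervals:
            if not (0 <= s <= e < n_frames):
                raise ValueError(f"interval ({h},{a},{s},{e}) outside trajectory")
            seen.setdefault((h, a), []).append((s, e))
        for pair, ivs in seen.items():
            ivs.sort()
            for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                if s2 <= e1:
                    raise ValueError(f"overlapping intervals for pair {pair}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.intervals,
            columns=["donor_id", "acceptor_id", "start_frame", "end_frame"],
        )


# ---------------------------------------------------------------------------
# Geometry helpers
# ---------------------------------------------------------------------------

def _random_unit(rng: np.random.Generator, n: int = 1) -> np.ndarray:
    v = rng.standard_normal((n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def _place_bulk(rng, box, sulfur_pos, n, min_from_s=6.0):
    """``n`` uniform positions in the box, all >= ``min_from_s`` (minimum
    image) from every sulfur; vectorized rejection sampling."""
    sulfur_pos = np.atleast_2d(sulfur_pos)
    pts = rng.uniform(0, 1, (n, 3)) * box
    for _ in range(200):
        d = pts[:, None, :] - sulfur_pos[None, :, :]
        d -= box * np.round(d / box)
        bad = (np.linalg.norm(d, axis=2) < min_from_s).any(axis=1)
        if not bad.any():
            return pts
        pts[bad] = rng.uniform(0, 1, (int(bad.sum()), 3)) * box
    raise RuntimeError("box too small to keep waters out of the solvation shell")


def _waters_at(o_pos: np.ndarray, h1_dir: np.ndarray, rng) -> np.ndarray:
    """Vectorized water construction: (m, 3, 3) coordinates with the first
    hydrogen of each water along its row of ``h1_dir``."""
    m = o_pos.shape[0]
    h1 = h1_dir / np.linalg.norm(h1_dir, axis=1, keepdims=True)
    perp = np.cross(h1, _random_unit(rng, m))
    nrm = np.linalg.norm(perp, axis=1, keepdims=True)
    low = nrm[:, 0] < 1e-8
    if low.any():
        perp[low] = np.cross(h1[low], _random_unit(rng, int(low.sum())))
        nrm = np.linalg.norm(perp, axis=1, keepdims=True)
    perp /= nrm
    h2 = np.cos(_HOH) * h1 + np.sin(_HOH) * perp
    out = np.empty((m, 3, 3))
    out[:, 0] = o_pos
    out[:, 1] = o_pos + _OH * h1
    out[:, 2] = o_pos + _OH * h2
    return out


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

def auto_schedule(
    solute_kind: str,
    n_waters: int,
    n_frames: int,
    water_h_ids,
    water_o_ids,
    sulfur_ids,
    sulfur_h_id,
    mean_residence: float = 20.0,
    occupancy: float = 0.6,
    seed: int = 0,
) -> BondSchedule:
    """Random schedule with geometric-ish interval lengths.

    ``occupancy`` is the target mean number of simultaneous bonds per frame
    and per direction (O-H...S always; S-H...O only for a thiol solute).
    S-H...O intervals are laid out serially in time — the single thiol
    hydrogen donates to one water at a time.
    """
    rng = np.random.default_rng(seed)
    sched = BondSchedule()

    def draw_len():
        return int(min(n_frames, max(1, rng.geometric(1.0 / mean_residence))))

    # O-H...S: independent intervals, any water may donate to any sulfur.
    target_frames = occupancy * n_frames * len(sulfur_ids)
    acc = 0.0
    w_idx = 0
    while acc < target_frames and w_idx < n_waters:
        L = draw_len()
        start = int(rng.integers(0, max(1, n_frames - L + 1)))
        h = int(water_h_ids[2 * w_idx])          # first hydrogen of water w_idx
        s = int(rng.choice(sulfur_ids))
        sched.intervals.append((h, s, start, start + L - 1))
        acc += L
        w_idx += 1

    # S-H...O: serial occupancy of the single donor hydrogen (thiol only).
    if solute_kind == "thiol":
        t = 0
        w2 = w_idx
        while t < int(occupancy * n_frames) and w2 < n_waters:
            L = draw_len()
            o = int(water_o_ids[w2])
            sched.intervals.append((int(sulfur_h_id), o, t, min(n_frames - 1, t + L - 1)))
            t += L + 1
            w2 += 1
    return sched


def generate_solvation_trajectory(
    solute_kind: str = "thiol",
    n_waters: int = 200,
    n_frames: int = 2000,
    box=(30.0, 30.0, 30.0),
    schedule: BondSchedule | None = None,
    mean_residence: float = 20.0,
    occupancy: float = 0.6,
    seed: int = 0,
):
    """Generate a (Trajectory, BondSchedule) pair.

    ``solute_kind`` is ``"thiol"`` (one S, one S-bonded H) or
    ``"disulfide"`` (two S, no S-bonded H).  If no schedule is given one is
    drawn with :func:`auto_schedule`.  Scheduled geometry: donor-acceptor
    distance U(3.0, 3.6) A for O...S and U(2.7, 3.2) A for O...O, with the
    D-H...A angle in U(160, 180) degrees — inside the default detection
    criteria with margin.  Off-interval and unscheduled waters are uniform
    in bulk, >= 6 A from every sulfur, re-placed every frame.
    """
    if solute_kind not in ("thiol", "disulfide"):
        raise ValueError("solute_kind must be 'thiol' or 'disulfide'")
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    box = np.asarray(box, dtype=float)
    rng = np.random.default_rng(seed)
    center = box / 2.0

    # --- topology ---------------------------------------------------------
    elements, roles, mol_ids = [], [], []
    bonds: dict = {}
    if solute_kind == "thiol":
        elements += ["S", "H"]
        roles += ["sulfur", "sulfur_hydrogen"]
        mol_ids += [0, 0]
        bonds[1] = 0
        sulfur_ids = [0]
        sulfur_h_id = 1
        solute_xyz = np.array([center, center + np.array([_SH, 0.0, 0.0])])
        sh_axis = np.array([1.0, 0.0, 0.0])
    else:
        elements += ["S", "S"]
        roles += ["sulfur", "sulfur"]
        mol_ids += [0, 0]
        sulfur_ids = [0, 1]
        sulfur_h_id = None
        half = np.array([_SS / 2.0, 0.0, 0.0])
        solute_xyz = np.array([center - half, center + half])
        sh_axis = None
    n_solute = len(elements)

    water_o_ids, water_h_ids = [], []
    for w in range(n_waters):
        o = n_solute + 3 * w
        elements += ["O", "H", "H"]
        roles += ["water_oxygen", "water_hydrogen", "water_hydrogen"]
        mol_ids += [1 + w] * 3
        bonds[o + 1] = o
        bonds[o + 2] = o
        water_o_ids.append(o)
        water_h_ids += [o + 1, o + 2]
    topo = Topology(elements, roles, mol_ids, bonds)

    if schedule is None:
        schedule = auto_schedule(
            solute_kind, n_waters, n_frames, water_h_ids, water_o_ids,
            sulfur_ids, sulfur_h_id, mean_residence, occupancy,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
    schedule.validate(n_frames)
    for h, a, s, e in schedule.intervals:
        if topo.roles[h] in ("sulfur_hydrogen", "water_hydrogen"):
            continue
        if solute_kind == "disulfide":
            raise ValueError("schedule requests S-H...O but the disulfide "
                             "solute has no sulfur-bonded hydrogen")
        raise ValueError(f"atom {h} is not a donor hydrogen")

    # per-frame lookup: water molecule -> active scheduled bond
    active: dict = {}
    for h, a, s, e in schedule.intervals:
        if topo.roles[h] == "water_hydrogen":
            w = (h - n_solute) // 3
        else:
            w = (a - n_solute) // 3
        for f in range(s, e + 1):
            active.setdefault(f, {})[w] = (h, a)

    sulfur_pos = solute_xyz[sulfur_ids]
    frames = np.empty((n_frames, topo.n_atoms, 3))
    for f in range(n_frames):
        coords = np.empty((topo.n_atoms, 3))
        coords[:n_solute] = solute_xyz
        act = active.get(f, {})
        for w, (h, a) in act.items():
            o_id = water_o_ids[w]
            if topo.roles[h] == "water_hydrogen":
                # O-H...S: O in the 3.0-3.6 A shell of sulfur `a`, donor
                # hydrogen pointed at S within 20 deg of linear.  Reject
                # geometries that would *also* satisfy (or come within the
                # safety margin of) the detection criteria for any other
                # donor-hydrogen/sulfur combination: the other sulfur of a
                # disulfide sits only ~2 A away, and in a thiol the S-H
                # axis must not point at the placed oxygen.
                s_pos = solute_xyz[a]
                for _try in range(200):
                    d = rng.uniform(3.0, 3.6)
                    u = _random_unit(rng)[0]
                    o_pos = s_pos + d * u
                    if sh_axis is not None and _angle_at(
                        solute_xyz[sulfur_h_id], solute_xyz[0], o_pos
                    ) >= 140.0:
                        continue
                    to_s = (s_pos - o_pos) / d
                    dev = np.deg2rad(rng.uniform(0.0, 20.0))
                    h_dir = _tilt(to_s, dev, rng)
                    water = _waters_at(o_pos[None], h_dir[None], rng)[0]
                    if h == o_id + 2:          # scheduled donor is H2
                        water = water[[0, 2, 1]]
                    if _clean_shell_water(water, h - o_id, a, solute_xyz,
                                          sulfur_ids):
                        break
                else:
                    raise RuntimeError("could not realize scheduled O-H...S "
                                       "geometry without side bonds")
            else:
                # S-H...O: water O near the S-H axis so the S-H...O angle
                # is within 20 deg of linear at 3.0-3.6 A from S.  Water
                # hydrogens point away from S (no spurious O-H...S).
                s_pos = solute_xyz[topo.bonds[h]]
                h_pos = solute_xyz[h]
                for _try in range(200):
                    d = rng.uniform(3.0, 3.6)
                    dev = np.deg2rad(rng.uniform(0.0, 20.0))
                    o_dir = _tilt(sh_axis, dev, rng)
                    o_pos = h_pos + o_dir * _dist_from_h(d, dev)
                    away = (o_pos - s_pos) / np.linalg.norm(o_pos - s_pos)
                    water = _waters_at(o_pos[None], away[None], rng)[0]
                    if _clean_shell_water(water, 0, -1, solute_xyz, sulfur_ids):
                        break
                else:
                    raise RuntimeError("could not realize scheduled S-H...O "
                                       "geometry without side bonds")
            coords[o_id:o_id + 3] = water

        bulk_w = [w for w in range(n_waters) if w not in act]
        if bulk_w:
            o_pos = _place_bulk(rng, box, sulfur_pos, len(bulk_w))
            waters = _waters_at(o_pos, _random_unit(rng, len(bulk_w)), rng)
            for j, w in enumerate(bulk_w):
                coords[water_o_ids[w]:water_o_ids[w] + 3] = waters[j]
        frames[f] = coords

    return Trajectory(box=box, frames=frames, topology=topo), schedule


def _clean_shell_water(water, donor_slot, scheduled_s, solute_xyz,
                       sulfur_ids) -> bool:
    """True iff the placed water realizes O-H...S geometry *only* for its
    scheduled (donor hydrogen, sulfur) pair, with a safety margin (>= 5 A
    or <= 140 deg) for every other hydrogen/sulfur combination."""
    o = water[0]
    for slot in (1, 2):
        hpos = water[slot]
        for s in sulfur_ids:
            if slot == donor_slot and s == scheduled_s:
                continue
            d = np.linalg.norm(o - solute_xyz[s])
            if d < 5.0 and _angle_at(hpos, o, solute_xyz[s]) > 140.0:
                return False
    return True


def _angle_at(vertex, p1, p2) -> float:
    """Angle p1-vertex-p2 in degrees."""
    v1 = p1 - vertex
    v2 = p2 - vertex
    c = float(v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2)))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def _tilt(axis: np.ndarray, angle: float, rng) -> np.ndarray:
    """Unit vector at ``angle`` radians from ``axis`` (random azimuth)."""
    axis = axis / np.linalg.norm(axis)
    perp = np.cross(axis, _random_unit(rng)[0])
    while np.linalg.norm(perp) < 1e-8:
        perp = np.cross(axis, _random_unit(rng)[0])
    perp /= np.linalg.norm(perp)
    return np.cos(angle) * axis + np.sin(angle) * perp


def _dist_from_h(d_sa: float, dev: float) -> float:
    """Distance |H-A| so that |S-A| = d_sa when A sits at angular deviation
    ``dev`` (radians) from the S-H axis measured at H.

    Law of cosines in triangle S-H-A with |S-H| = _SH and the angle at H
    equal to pi - dev (near-linear S-H...A).
    """
    cos_at_h = np.cos(np.pi - dev)
    # |SA|^2 = |SH|^2 + |HA|^2 - 2 |SH||HA| cos(angle at H)
    a, b, c = 1.0, -2.0 * _SH * cos_at_h, _SH**2 - d_sa**2
    return (-b + np.sqrt(b * b - 4 * a * c)) / (2 * a)


def ideal_gas_frames(n_points: int, box=(30.0, 30.0, 30.0),
                     n_frames: int = 100, seed: int = 0) -> Trajectory:
    """Uniform points per frame plus one fixed reference atom at the box
    center: the analytic g(r) = 1 oracle for the RDF machinery."""
    if n_points < 2:
        raise ValueError("need at least 2 points")
    box = np.asarray(box, dtype=float)
    rng = np.random.default_rng(seed)
    elements = ["S"] + ["O"] * n_points
    roles = ["sulfur"] + ["water_oxygen"] * n_points
    mol_ids = list(range(n_points + 1))
    topo = Topology(elements, roles, mol_ids, bonds={})
    frames = np.empty((n_frames, n_points + 1, 3))
    frames[:, 0] = box / 2.0
    frames[:, 1:] = rng.uniform(0, 1, (n_frames, n_points, 3)) * box
    return Trajectory(box=box, frames=frames, topology=topo)


# ---------------------------------------------------------------------------
# File formats: multi-frame XYZ + JSON topology + CSV schedule
# ---------------------------------------------------------------------------

def write_xyz(traj: Trajectory, path) -> None:
    with open(path, "w") as fh:
        n = traj.topology.n_atoms
        for f in range(traj.n_frames):
            fh.write(f"{n}\n")
            bx = " ".join(f"{b:.4f}" for b in traj.box)
            fh.write(f"frame {f} box {bx}\n")
            for el, (x, y, z) in zip(traj.topology.elements, traj.frames[f]):
                fh.write(f"{el} {x:.6f} {y:.6f} {z:.6f}\n")


def write_topology(traj: Trajectory, path) -> None:
    topo = traj.topology
    payload = {
        "box": traj.box.tolist(),
        "frame_spacing_ps": traj.frame_spacing_ps,
        "atoms": [
            {"index": i, "element": topo.elements[i], "role": topo.roles[i],
             "molecule_id": topo.molecule_ids[i]}
            for i in range(topo.n_atoms)
        ],
        "bonds": [{"hydrogen": int(h), "heavy": int(a)}
                  for h, a in sorted(topo.bonds.items())],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def write_schedule(schedule: BondSchedule, path) -> None:
    schedule.to_frame().to_csv(path, index=False)


def read_schedule(path) -> BondSchedule:
    df = pd.read_csv(path)
    return BondSchedule(intervals=[tuple(int(v) for v in row)
                                   for row in df.to_numpy()])
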