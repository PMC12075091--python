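"""Hydration-shell analysis of solvation trajectories.

Reproduces the trajectory half of the redox-identification analysis:

* sulfur-water radial distribution functions g(r) under orthorhombic
  periodic boundary conditions (minimum image), with first-peak location
  and the coordination-number integral N(r) = 4 pi rho \\int g r^2 dr;
* geometric hydrogen-bond detection with explicit directionality — water
  donating to sulfur (O-H...S), the thiol hydrogen donating to water
  (S-H...O), and water-water (O-H...O);
* maximal bonded-frame intervals per directed donor/acceptor pair
  (residence bookkeeping) and the residence-time-weighted interaction
  score, the tally that separates a thiol sulfur (donor *and* acceptor)
  from a disulfide sulfur (acceptor only: its S-H...O score is a
  structural zero).

A hydrogen bond D-H...A is declared when the donor-acceptor minimum-image
distance is within an element-pair cutoff (defaults: 3.5 A for O...O,
4.0 A for O...S — just beyond the ~3.8 A first peak of the S-water RDF)
and the D-H...A angle is within 30 degrees of linear.  The criteria are
configurable per element pair.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from aquaredox.synthetic_trajectory import BondSchedule, Topology, Trajectory

DIRECTIONS = ("OH-S", "SH-O", "OH-O")


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric hydrogen-bond definition."""

    max_distance: dict = field(
        default_factory=lambda: {("O", "O"): 3.5, ("O", "S"): 4.0}
    )   # donor-acceptor element pair (sorted) -> cutoff, A
    max_angle_deviation_deg: float = 30.0   # from linear D-H...A

    def __post_init__(self):
        if any(d <= 0 for d in self.max_distance.values()):
            raise ValueError("distance cutoffs must be positive")
        if not 0 < self.max_angle_deviation_deg < 90:
            raise ValueError("angle deviation must be in (0, 90) degrees")

    def cutoff(self, el1: str, el2: str) -> float:
        key = tuple(sorted((el1, el2)))
        try:
            return self.max_distance[key]
        except KeyError:
            raise KeyError(f"no distance cutoff for element pair {key}") from None


# ---------------------------------------------------------------------------
# Trajectory I/O (formats written by synthetic_trajectory)
# ---------------------------------------------------------------------------

def read_trajectory(xyz_path, topology_path) -> Trajectory:
    """Read a multi-frame XYZ file plus its JSON topology sidecar."""
    with open(topology_path) as fh:
        topo_json = json.load(fh)
    atoms = sorted(topo_json["atoms"], key=lambda a: a["index"])
    roles = [a["role"] for a in atoms]
    for a in atoms:
        if a.get("role") is None:
            raise ValueError(f"atom {a['index']} has no role")
    topo = Topology(
        elements=[a["element"] for a in atoms],
        roles=roles,
        molecule_ids=[a["molecule_id"] for a in atoms],
        bonds={b["hydrogen"]: b["heavy"] for b in topo_json["bonds"]},
    )
    n_atoms = topo.n_atoms

    frames = []
    with open(xyz_path) as fh:
        lines = fh.read().splitlines()
    i = 0
    f_idx = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            count = int(lines[i].strip())
        except ValueError as exc:
            raise ValueError(f"bad XYZ atom-count line at line {i + 1}") from exc
        if count != n_atoms:
            raise ValueError(
                f"frame {f_idx} has {count} atoms, topology has {n_atoms}"
            )
        block = lines[i + 2:i + 2 + count]
        if len(block) < count:
            raise ValueError(f"frame {f_idx} truncated")
        coords = np.array(
            [[float(v) for v in ln.split()[1:4]] for ln in block]
        )
        frames.append(coords)
        i += 2 + count
        f_idx += 1
    return Trajectory(
        box=np.asarray(topo_json["box"], dtype=float),
        frames=np.stack(frames),
        topology=topo,
        frame_spacing_ps=float(topo_json.get("frame_spacing_ps", 10.0)),
    )


# ---------------------------------------------------------------------------
# Geometry under orthorhombic PBC
# ---------------------------------------------------------------------------

def _min_image(d: np.ndarray, box: np.ndarray) -> np.ndarray:
    return d - box * np.round(d / box)


# ---------------------------------------------------------------------------
# RDF
# ---------------------------------------------------------------------------

@dataclass
class RDFProfile:
    bin_centers: np.ndarray     # A
    g: np.ndarray
    bin_width: float
    reference_role: str
    target_role: str
    n_frames: int
    bulk_density: float         # A^-3, target number density in the box


def compute_rdf(traj: Trajectory, reference_role: str = "sulfur",
                target_role: str = "water_oxygen", bin_width: float = 0.1,
                r_max: float | None = None) -> RDFProfile:
    """Radial distribution function of target atoms around reference atoms.

    g(r) = <pair count in shell> / (N_ref * rho_target * V_shell), averaged
    over frames, with minimum-image distances and shell volumes
    (4/3) pi (r2^3 - r1^3).  ``r_max`` defaults to (and may not exceed)
    half the smallest box edge.
    """
    box = traj.box
    half = float(box.min()) / 2.0
    r_max = half if r_max is None else float(r_max)
    if r_max > half + 1e-9:
        raise ValueError(f"r_max={r_max} exceeds half the box ({half})")
    ref = traj.topology.atoms_with_role(reference_role)
    tgt = traj.topology.atoms_with_role(target_role)
    if ref.size == 0 or tgt.size == 0:
        raise ValueError(
            f"no atoms with role {reference_role!r} or {target_role!r}"
        )
    edges = np.arange(0.0, r_max + bin_width, bin_width)
    edges = edges[edges <= r_max + 1e-12]
    counts = np.zeros(edges.size - 1)
    for f in range(traj.n_frames):
        d = traj.frames[f][tgt][None, :, :] - traj.frames[f][ref][:, None, :]
        r = np.linalg.norm(_min_image(d, box), axis=2).ravel()
        r = r[r > 1e-9]     # drop self pairs if roles overlap
        counts += np.histogram(r, bins=edges)[0]
    counts /= traj.n_frames
    rho = tgt.size / float(np.prod(box))
    shell_vol = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    g = counts / (ref.size * rho * shell_vol)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return RDFProfile(centers, g, bin_width, reference_role, target_role,
                      traj.n_frames, rho)


def first_peak(profile: RDFProfile, search_range=(2.0, 5.0), min_g: float = 0.0):
    """Location and height of the first local maximum of g(r) in the range.

    ``min_g`` ignores local maxima at or below that height (useful for
    skipping noise ripples in depleted regions).
    """
    lo, hi = search_range
    sel = (profile.bin_centers >= lo) & (profile.bin_centers <= hi)
    idx = np.where(sel)[0]
    if idx.size < 3:
        raise ValueError("search range covers too few bins")
    g = profile.g
    for i in idx:
        if i == 0 or i == g.size - 1:
            continue
        if g[i] > min_g and g[i] >= g[i - 1] and g[i] > g[i + 1]:
            return float(profile.bin_centers[i]), float(g[i])
    raise ValueError("no local maximum of g(r) in the search range")


def coordination_number(profile: RDFProfile, r_cut: float) -> float:
    """N(r_cut) = 4 pi rho int_0^{r_cut} g(r) r^2 dr (trapezoidal)."""
    r = profile.bin_centers
    if r_cut > r[-1] + profile.bin_width:
        raise ValueError("r_cut beyond profile range")
    sel = r <= r_cut
    rr = np.concatenate([[0.0], r[sel]])
    gg = np.concatenate([[0.0], profile.g[sel]])
    integrand = gg * rr**2
    return float(4.0 * np.pi * profile.bulk_density * np.trapezoid(integrand, rr))


# ---------------------------------------------------------------------------
# Hydrogen bonds
# ---------------------------------------------------------------------------

def _donor_table(topo: Topology):
    """Arrays (hydrogen ids, donor heavy ids, donor elements)."""
    hs, heavies = [], []
    for i, role in enumerate(topo.roles):
        if role in ("water_hydrogen", "sulfur_hydrogen"):
            if i not in topo.bonds:
                raise ValueError(f"hydrogen {i} has no bonded heavy atom")
            hs.append(i)
            heavies.append(topo.bonds[i])
    return np.array(hs, dtype=int), np.array(heavies, dtype=int)


def _class_bonds(frame, box, h_ids, heavy_ids, acc_ids, cutoffs, min_angle,
                 direction, out):
    """Vectorized D-H...A detection for one donor/acceptor class."""
    if h_ids.size == 0 or acc_ids.size == 0:
        return
    dvec = _min_image(frame[acc_ids][None, :, :] - frame[heavy_ids][:, None, :],
                      box)
    dist = np.linalg.norm(dvec, axis=2)
    near = dist <= cutoffs[None, :]
    # a heavy atom cannot accept from its own hydrogen
    near &= heavy_ids[:, None] != acc_ids[None, :]
    if not near.any():
        return
    ii, jj = np.nonzero(near)
    hvec = _min_image(frame[heavy_ids[ii]] - frame[h_ids[ii]], box)
    avec = _min_image(frame[acc_ids[jj]] - frame[h_ids[ii]], box)
    cosang = np.einsum("ij,ij->i", hvec, avec) / (
        np.linalg.norm(hvec, axis=1) * np.linalg.norm(avec, axis=1) + 1e-300
    )
    ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    ok = ang >= min_angle
    for i, j, r, th in zip(ii[ok], jj[ok], dist[near][ok], ang[ok]):
        out.append((int(h_ids[i]), int(acc_ids[j]), direction,
                    float(r), float(th)))


def detect_hbonds(frame: np.ndarray, topology: Topology, box,
                  criteria: HBondCriteria | None = None,
                  directions=DIRECTIONS) -> list:
    """All geometric hydrogen bonds in one frame.

    Returns tuples ``(donor_hydrogen_id, acceptor_id, direction,
    distance_A, angle_deg)``; the donor heavy atom is
    ``topology.bonds[donor_hydrogen_id]``.  ``directions`` restricts which
    directional classes are evaluated (water-water detection over all pairs
    is the expensive one).
    """
    criteria = criteria or HBondCriteria()
    box = np.asarray(box, dtype=float)
    frame = np.asarray(frame, dtype=float)
    topo = topology
    hs, heavies = _donor_table(topo)
    water_h = np.array([h for h, hv in zip(hs, heavies)
                        if topo.roles[hv] == "water_oxygen"], dtype=int)
    water_h_heavy = np.array([topo.bonds[h] for h in water_h], dtype=int)
    sulf_h = np.array([h for h, hv in zip(hs, heavies)
                       if topo.roles[hv] == "sulfur"], dtype=int)
    sulf_h_heavy = np.array([topo.bonds[h] for h in sulf_h], dtype=int)
    sulfurs = topo.atoms_with_role("sulfur")
    oxygens = topo.atoms_with_role("water_oxygen")

    min_angle = 180.0 - criteria.max_angle_deviation_deg
    out: list = []

    def cuts(d_heavy_ids, acc_ids):
        d_el = topo.elements[int(d_heavy_ids[0])]
        return np.array([criteria.cutoff(d_el, topo.elements[int(a)])
                         for a in acc_ids])

    if "OH-S" in directions and water_h.size and sulfurs.size:
        _class_bonds(frame, box, water_h, water_h_heavy, sulfurs,
                     cuts(water_h_heavy, sulfurs), min_angle, "OH-S", out)
    if "SH-O" in directions and sulf_h.size and oxygens.size:
        _class_bonds(frame, box, sulf_h, sulf_h_heavy, oxygens,
                     cuts(sulf_h_heavy, oxygens), min_angle, "SH-O", out)
    if "OH-O" in directions and water_h.size and oxygens.size:
        _class_bonds(frame, box, water_h, water_h_heavy, oxygens,
                     cuts(water_h_heavy, oxygens), min_angle, "OH-O", out)
    return out


@dataclass
class BondIntervalSet:
    """Maximal consecutive bonded-frame runs per directed pair."""

    intervals: dict = field(default_factory=dict)
    # (donor_h_id, acceptor_id, direction) -> list of (start, end) inclusive
    window: tuple = (0, 0)

    def lengths(self, direction: str) -> list:
        out = []
        for (h, a, d), ivs in self.intervals.items():
            if d == direction:
                out += [e - s + 1 for s, e in ivs]
        return out


def bond_intervals(traj: Trajectory, criteria: HBondCriteria | None = None,
                   window=None, directions=("OH-S", "SH-O")) -> BondIntervalSet:
    """Maximal runs of consecutive bonded frames per directed pair.

    ``window`` is (first_frame, last_frame) inclusive; default the whole
    trajectory.  By default only the sulfur-involving directions are
    tracked; pass ``directions=DIRECTIONS`` to include water-water bonds.
    """
    lo, hi = (0, traj.n_frames - 1) if window is None else window
    if not (0 <= lo <= hi < traj.n_frames):
        raise ValueError(f"window ({lo}, {hi}) invalid for {traj.n_frames} frames")
    open_runs: dict = {}
    closed: dict = {}
    for f in range(lo, hi + 1):
        bonds = detect_hbonds(traj.frames[f], traj.topology, traj.box,
                              criteria, directions=directions)
        now = {(h, a, d) for h, a, d, _, _ in bonds}
        for key in list(open_runs):
            if key not in now:
                s = open_runs.pop(key)
                closed.setdefault(key, []).append((s, f - 1))
        for key in now:
            open_runs.setdefault(key, f)
    for key, s in open_runs.items():
        closed.setdefault(key, []).append((s, hi))
    for ivs in closed.values():
        ivs.sort()
    return BondIntervalSet(intervals=closed, window=(lo, hi))


@dataclass
class InteractionScore:
    direction: str
    window: tuple
    min_persistence: int
    weight_exponent: float
    value: float                # residence-weighted tally, frames
    n_intervals: int


def interaction_score(intervals: BondIntervalSet, direction: str,
                      min_persistence: int = 1,
                      weight_exponent: float = 0.0) -> InteractionScore:
    """Residence-time-weighted hydrogen-bond tally for one direction.

    score = sum over maximal intervals of length L >= min_persistence of
    L^(1 + weight_exponent).  With the defaults (min_persistence 1,
    exponent 0) this is the total number of bonded frames — each bond
    contributes once per frame it persists, i.e. bonds weighted by their
    residence time.
    """
    if direction not in ("OH-S", "SH-O"):
        raise ValueError("direction must be 'OH-S' or 'SH-O'")
    lens = [L for L in intervals.lengths(direction) if L >= min_persistence]
    value = float(sum(L ** (1.0 + weight_exponent) for L in lens))
    return InteractionScore(direction, intervals.window, min_persistence,
                            weight_exponent, value, len(lens))


def per_sulfur_summary(scores: dict, n_sulfur: int) -> dict:
    """Totals and per-sulfur-normalized scores.

    ``scores`` maps direction -> InteractionScore (or raw value).  The
    combined score is OH-S + SH-O; normalization divides by the number of
    sulfur atoms, the comparison that puts a disulfide (two sulfurs) on the
    same footing as two thiols.
    """
    if n_sulfur < 1:
        raise ValueError("n_sulfur must be >= 1")
    vals = {
        d: (s.value if isinstance(s, InteractionScore) else float(s))
        for d, s in scores.items()
    }
    total = sum(vals.get(d, 0.0) for d in ("OH-S", "SH-O"))
    return {
        "per_direction": vals,
        "total": total,
        "per_sulfur": {d: v / n_sulfur for d, v in vals.items()},
        "total_per_sulfur": total / n_sulfur,
        "n_sulfur": n_sulfur,
    }


def intervals_to_schedule(intervals: BondIntervalSet) -> BondSchedule:
    """Express recovered sulfur-direction intervals as a BondSchedule (for
    closed-loop comparison with the generator's ground truth)."""
    out = BondSchedule()
    for (h, a, d), ivs in intervals.intervals.items():
        if d in ("OH-S", "SH-O"):
            for s, e in ivs:
                out.intervals.append((h, a, s, e))
    out.intervals.sort()
    return out


def write_rdf_csv(profile: RDFProfile, path) -> None:
    pd.DataFrame({"r_A": profile.bin_centers, "g": profile.g}).to_csv(
        path, index=False
    )


def write_intervals_csv(intervals: BondIntervalSet, path) -> None:
    rows = [
        {"donor_id": h, "acceptor_id": a, "direction": d,
         "start_frame": s, "end_frame": e, "length": e - s + 1}
        for (h, a, d), ivs in sorted(intervals.intervals.items())
        for s, e in ivs
    ]
    pd.DataFrame(
        rows, columns=["donor_id", "acceptor_id", "direction",
                       "start_frame", "end_frame", "length"]
    ).to_csv(path, index=False)
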