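"""Independent brute-force oracles used by the test suite.

Deliberately naive: plain Python loops and scalar math, sharing no code
with the implementation under test.
"""

import math


def _mi(dx, b):
    return dx - b * round(dx / b)


def _dist(p, q, box):
    return math.sqrt(sum(_mi(p[k] - q[k], box[k]) ** 2 for k in range(3)))


def _angle_deg(vertex, p1, p2, box):
    v1 = [_mi(p1[k] - vertex[k], box[k]) for k in range(3)]
    v2 = [_mi(p2[k] - vertex[k], box[k]) for k in range(3)]
    dot = sum(a * b for a, b in zip(v1, v2))
    n1 = math.sqrt(sum(a * a for a in v1))
    n2 = math.sqrt(sum(a * a for a in v2))
    c = max(-1.0, min(1.0, dot / (n1 * n2)))
    return math.degrees(math.acos(c))


def brute_force_sulfur_bonds(traj, cutoff_os=4.0, max_dev=30.0):
    """Per-frame bonded flags for every sulfur-involving directed pair.

    Returns ``{(h_id, acc_id, direction): [bonded frame indices]}`` by
    looping over frames x donors x acceptors with scalar arithmetic.
    """
    topo = traj.topology
    box = [float(b) for b in traj.box]
    sulfurs = [i for i, r in enumerate(topo.roles) if r == "sulfur"]
    oxygens = [i for i, r in enumerate(topo.roles) if r == "water_oxygen"]
    water_h = [i for i, r in enumerate(topo.roles) if r == "water_hydrogen"]
    sulf_h = [i for i, r in enumerate(topo.roles) if r == "sulfur_hydrogen"]
    min_angle = 180.0 - max_dev

    bonded = {}
    for f in range(traj.n_frames):
        pos = traj.frames[f]
        for h in water_h:                       # O-H...S
            o = topo.bonds[h]
            for s in sulfurs:
                if _dist(pos[o], pos[s], box) <= cutoff_os:
                    if _angle_deg(pos[h], pos[o], pos[s], box) >= min_angle:
                        bonded.setdefault((h, s, "OH-S"), []).append(f)
        for h in sulf_h:                        # S-H...O
            s = topo.bonds[h]
            for o in oxygens:
                if _dist(pos[s], pos[o], box) <= cutoff_os:
                    if _angle_deg(pos[h], pos[s], pos[o], box) >= min_angle:
                        bonded.setdefault((h, o, "SH-O"), []).append(f)
    return bonded


def brute_force_score(traj, direction, min_persistence=1, weight_exponent=0.0,
                      bonded=None):
    """Residence-weighted tally from the per-frame oracle: split each
    pair's bonded-frame list into maximal runs, then sum L^(1+exponent)
    over runs with L >= min_persistence."""
    if bonded is None:
        bonded = brute_force_sulfur_bonds(traj)
    total = 0.0
    for (h, a, d), frames in bonded.items():
        if d != direction:
            continue
        run = 1
        lengths = []
        for prev, cur in zip(frames, frames[1:]):
            if cur == prev + 1:
                run += 1
            else:
                lengths.append(run)
                run = 1
        lengths.append(run)
        total += sum(
            L ** (1.0 + weight_exponent) for L in lengths if L >= min_persistence
        )
    return total


def direct_shell_count(traj, r_cut):
    """Frame-averaged count of water oxygens within r_cut of a (single)
    sulfur reference — the counting oracle for the RDF integral."""
    topo = traj.topology
    box = [float(b) for b in traj.box]
    sulfurs = [i for i, r in enumerate(topo.roles) if r == "sulfur"]
    oxygens = [i for i, r in enumerate(topo.roles) if r == "water_oxygen"]
    total = 0
    for f in range(traj.n_frames):
        pos = traj.frames[f]
        for s in sulfurs:
            for o in oxygens:
                if o != s and _dist(pos[s], pos[o], box) <= r_cut:
                    total += 1
    return total / (traj.n_frames * len(sulfurs))
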