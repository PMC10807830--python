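"""Ground-truth-labelled synthetic inputs for every pipeline stage.

The generator emulates the statistical structure the analyses assume,
without any physics: a three-domain Calpha pseudo-receptor (a leucine-rich
repeat solenoid, a flexible hinge loop with a short helical segment, and a
seven-helix transmembrane bundle), frame-to-frame Gaussian fluctuation
around a few discrete conformational states that differ in rigid domain
placements (tens of Angstrom at the anchors) and in an internal TM
distortion with a controlled fitted-RMSD amplitude, Markov switching
between states, an optional global rigid jitter per frame so that
superposition is genuinely exercised, and a slab-structured membrane box
(lipid tails / phosphate shells / water layers along z) for density tests.

Residue numbering follows the FSHR conventions (695 residues, TM helices at
362-392 ... 607-626), so the shipped FSHR geometry dictionary resolves
against the toy receptor unchanged. Everything is deterministic under the
spec seed.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .structure_io import StructureModel, TrajectoryEnsemble, write_pdb, write_trajectory
from .superposition import kabsch_fit

__all__ = [
    "StateDefinition",
    "SyntheticSpec",
    "generate_toy_receptor",
    "generate_trajectory",
    "generate_membrane_box",
    "simulate_state_path",
    "state_templates",
    "ground_truth_distance_series",
    "transition_from_dwell",
    "write_fixture_set",
    "TOY_N_RESIDUES",
    "TOY_DOMAIN_BOUNDS",
]

TOY_N_RESIDUES = 695
#: residue spans of the three rigid domains (N-terminus counts with the LRR,
#: the C-tail with the TM bundle)
TOY_DOMAIN_BOUNDS = {"lrr": (1, 270), "hr": (271, 361), "tm": (362, 695)}

_TM_RANGES = ((362, 392), (397, 432), (437, 472), (487, 507),
              (532, 557), (567, 597), (607, 626))
_HR_HELIX = (298, 308)          # 11-residue hinge alpha-helix, anchor Y303 mid-helix

_HELIX_RISE = 1.5               # Angstrom per residue along the axis
_HELIX_TWIST = 100.0            # degrees per residue
_HELIX_RADIUS = 2.3             # Calpha radius of an ideal alpha-helix
_CA_SPACING = 3.8


# ---------------------------------------------------------------------------
# toy receptor geometry
# ---------------------------------------------------------------------------

def _helix_points(n: int, origin: np.ndarray, axis: np.ndarray,
                  phase_deg: float = 0.0) -> np.ndarray:
    """Ideal alpha-helix Calpha trace along ``axis`` starting at ``origin``."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    ref = np.array([1.0, 0.0, 0.0])
    if abs(axis @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(axis, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    t = np.arange(n)
    ang = np.deg2rad(_HELIX_TWIST * t + phase_deg)
    return (np.asarray(origin)
            + np.outer(_HELIX_RISE * t, axis)
            + _HELIX_RADIUS * (np.outer(np.cos(ang), e1) + np.outer(np.sin(ang), e2)))


def _resample_polyline(waypoints: Sequence, n: int) -> np.ndarray:
    """n points evenly spaced along the polyline through ``waypoints``."""
    pts = np.asarray(waypoints, dtype=float)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    target = np.linspace(0.0, s[-1], n)
    return np.column_stack([np.interp(target, s, pts[:, k]) for k in range(3)])


def generate_toy_receptor(n_residues: int = TOY_N_RESIDUES) -> StructureModel:
    """Calpha-only pseudo-receptor with FSHR-compatible residue numbering.

    Architecture: residues 18-270 form a leucine-rich-repeat-like solenoid
    high above the membrane plane, 271-361 an extended hinge loop carrying
    an ideal 11-residue alpha-helix (298-308), and 362-626 a bundle of seven
    ideal alpha-helices (rise 1.5 A, 100 deg/residue) on a 10 A-radius
    circle with connecting loops; short N- and C-terminal extensions
    complete the chain. The construction is deterministic.
    """
    if n_residues != TOY_N_RESIDUES:
        raise ValueError("the toy receptor is built with FSHR numbering "
                         f"({TOY_N_RESIDUES} residues)")
    xyz = np.zeros((n_residues, 3))
    placed = np.zeros(n_residues, dtype=bool)

    def put(resid: int, point: np.ndarray) -> None:
        xyz[resid - 1] = point
        placed[resid - 1] = True

    # --- TM bundle: seven ideal helices on a 10 A circle, alternating sense
    bundle_radius = 10.0
    for k, (a, b) in enumerate(_TM_RANGES):
        n = b - a + 1
        theta = 2.0 * np.pi * k / 7.0
        center = np.array([bundle_radius * np.cos(theta),
                           bundle_radius * np.sin(theta), 0.0])
        down = k % 2 == 0                      # odd-numbered helices run down
        half = 0.5 * _HELIX_RISE * (n - 1)
        origin = center + np.array([0.0, 0.0, half if down else -half])
        axis = np.array([0.0, 0.0, -1.0 if down else 1.0])
        pts = _helix_points(n, origin, axis, phase_deg=np.degrees(theta))
        for j, resid in enumerate(range(a, b + 1)):
            put(resid, pts[j])
    # loops between consecutive TM helices
    for (a0, b0), (a1, b1) in zip(_TM_RANGES[:-1], _TM_RANGES[1:]):
        gap = range(b0 + 1, a1)
        p, q = xyz[b0 - 1], xyz[a1 - 1]
        for j, resid in enumerate(gap, start=1):
            put(resid, p + (q - p) * j / (len(gap) + 1))

    # --- LRR solenoid (residues 18-270) above the membrane
    lrr_a, lrr_b = 18, 270
    n_lrr = lrr_b - lrr_a + 1
    dz = 0.30
    # chord of 3.8 A on a 14 A circle with 0.30 A rise per residue
    dtheta = 2.0 * np.arcsin(np.sqrt(_CA_SPACING**2 - dz**2) / (2.0 * 14.0))
    t = np.arange(n_lrr)
    lrr = np.column_stack([35.0 + 14.0 * np.cos(dtheta * t),
                           14.0 * np.sin(dtheta * t),
                           108.0 - dz * t])
    for j, resid in enumerate(range(lrr_a, lrr_b + 1)):
        put(resid, lrr[j])

    # --- N-terminal extension 1-17 leading into the solenoid
    start = lrr[0] + np.array([4.0, 3.0, 10.0])
    nterm = _resample_polyline([start, lrr[0] + np.array([1.0, 1.0, 2.5])], 17)
    for j, resid in enumerate(range(1, 18)):
        put(resid, nterm[j])

    # --- hinge region 271-361: loop, 11-residue helix, loop down to TM1
    lrr_end = lrr[-1]
    zig1 = _resample_polyline(
        [lrr_end + np.array([2.0, -4.0, -2.0]),
         np.array([22.0, -24.0, 34.0]),
         np.array([6.0, -34.0, 38.0])], _HR_HELIX[0] - 271)
    for j, resid in enumerate(range(271, _HR_HELIX[0])):
        put(resid, zig1[j])
    hr_helix = _helix_points(_HR_HELIX[1] - _HR_HELIX[0] + 1,
                             zig1[-1] + np.array([3.0, 0.0, 0.0]),
                             np.array([1.0, 0.0, 0.0]))
    for j, resid in enumerate(range(_HR_HELIX[0], _HR_HELIX[1] + 1)):
        put(resid, hr_helix[j])
    tm1_start = xyz[_TM_RANGES[0][0] - 1]
    zig2 = _resample_polyline(
        [hr_helix[-1] + np.array([2.0, 2.0, -2.0]),
         np.array([-2.0, -20.0, 32.0]),
         np.array([8.0, -8.0, 27.0]),
         tm1_start + np.array([-1.0, -1.0, 2.5])], 361 - _HR_HELIX[1])
    for j, resid in enumerate(range(_HR_HELIX[1] + 1, 362)):
        put(resid, zig2[j])

    # --- C-tail 627-695 below the membrane
    tm7_end = xyz[_TM_RANGES[-1][1] - 1]
    tail = _resample_polyline(
        [tm7_end + np.array([0.0, 0.0, -4.0]),
         np.array([2.0, 22.0, -30.0]),
         np.array([-20.0, 10.0, -36.0]),
         np.array([2.0, -12.0, -40.0])], 695 - 627 + 1)
    for j, resid in enumerate(range(627, 696)):
        put(resid, tail[j])

    assert placed.all(), "toy receptor construction left residues unplaced"
    resids = np.arange(1, n_residues + 1)
    return StructureModel(
        serial=resids.copy(),
        atom_name=np.full(n_residues, "CA"),
        element=np.full(n_residues, "C"),
        residue_number=resids,
        residue_name=np.full(n_residues, "ALA"),
        chain_id=np.full(n_residues, "A"),
        xyz=xyz,
        mass=np.full(n_residues, 12.011),
    )


# ---------------------------------------------------------------------------
# multi-state trajectory
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class StateDefinition:
    """One discrete conformational state of the toy receptor.

    ``anchor_offsets`` maps domain names ('lrr', 'hr', 'tm') to rigid
    displacement vectors (Angstrom) applied to every atom of the domain;
    ``tm_perturbation_rmsd`` sets the fitted-RMSD amplitude (Angstrom) of an
    internal, state-specific distortion of the TM bundle, which is what the
    TM-fitted RMSD matrix can see.
    """

    label: str
    anchor_offsets: dict[str, tuple[float, float, float]] = dataclasses.field(
        default_factory=dict)
    tm_perturbation_rmsd: float = 0.0

    def __post_init__(self) -> None:
        if self.tm_perturbation_rmsd < 0:
            raise ValueError("tm_perturbation_rmsd must be >= 0")
        unknown = set(self.anchor_offsets) - set(TOY_DOMAIN_BOUNDS)
        if unknown:
            raise ValueError(f"unknown domains in anchor_offsets: {sorted(unknown)}")


def _default_states() -> tuple[StateDefinition, ...]:
    """Two states mimicking the studied receptors' domain motions.

    State B lowers the LRR towards the membrane and pulls the hinge in
    towards the TM bundle, so all three anchor distances shift together by
    ~6-10 A (positively correlated, as observed for the follitropin
    receptor), and distorts the TM bundle by a fitted RMSD of 2.0 A --
    within the <3.1 A range seen for TM helices in equilibrium trajectories.
    """
    return (
        StateDefinition("A"),
        StateDefinition("B",
                        anchor_offsets={"lrr": (0.0, 0.0, -10.0),
                                        "hr": (-1.4, 5.4, -5.7)},
                        tm_perturbation_rmsd=2.0),
    )


def transition_from_dwell(mean_dwell_frames: Sequence[float]) -> np.ndarray:
    """Row-stochastic matrix with the given mean dwell times (frames).

    Each state exits with probability 1/dwell per frame, uniformly to the
    other states.
    """
    d = np.asarray(mean_dwell_frames, dtype=float)
    if np.any(d < 1):
        raise ValueError("mean dwell times must be >= 1 frame")
    k = d.size
    T = np.zeros((k, k))
    for i in range(k):
        p_exit = 1.0 / d[i]
        T[i] = p_exit / max(k - 1, 1)
        T[i, i] = 1.0 - p_exit if k > 1 else 1.0
    return T


@dataclasses.dataclass
class SyntheticSpec:
    """Full recipe for a labelled synthetic trajectory.

    Defaults are the study conditions of the receptor analyses this package
    implements: 10 ps frame interval, 0.2 A thermal noise, two states with a
    2.0 A inter-state TM distortion and ~100-frame dwells, 2000 frames,
    global rigid jitter on so superposition is genuinely exercised.
    """

    states: tuple[StateDefinition, ...] = dataclasses.field(
        default_factory=_default_states)
    transition: np.ndarray | None = None        # defaults to 100-frame dwells
    noise_sigma: float = 0.2
    n_frames: int = 2000
    frame_interval_ps: float = 10.0
    seed: int = 0
    rigid_jitter: bool = True
    jitter_translation: float = 5.0

    def __post_init__(self) -> None:
        if self.transition is None:
            self.transition = transition_from_dwell([100.0] * len(self.states))
        self.transition = np.asarray(self.transition, dtype=float)
        k = len(self.states)
        if self.transition.shape != (k, k):
            raise ValueError("transition matrix must be n_states x n_states")
        if not np.allclose(self.transition.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("transition matrix rows must sum to 1")
        if np.any(self.transition < 0):
            raise ValueError("transition probabilities must be >= 0")
        if self.noise_sigma < 0 or self.n_frames < 1:
            raise ValueError("noise_sigma must be >= 0 and n_frames >= 1")


def _domain_mask(model: StructureModel, domain: str) -> np.ndarray:
    a, b = TOY_DOMAIN_BOUNDS[domain]
    return (model.residue_number >= a) & (model.residue_number <= b)


def _tm_perturbation_field(model: StructureModel, target_rmsd: float,
                           rng: np.random.Generator) -> np.ndarray:
    """Internal TM distortion with a controlled fitted-RMSD amplitude.

    A random displacement field on the membrane-side atoms is iteratively
    rescaled so that the Kabsch-fitted RMSD between base and displaced
    TM-helix coordinates equals ``target_rmsd`` (rigid-body components of
    the random field would otherwise be absorbed by the fit). Calibration
    uses the seven helix ranges -- the selection the RMSD matrix measures.
    """
    field = np.zeros_like(model.xyz)
    if target_rmsd == 0.0:
        return field
    mask = _domain_mask(model, "tm")
    helix = np.zeros(model.n_atoms, dtype=bool)
    for a, b in _TM_RANGES:
        helix |= (model.residue_number >= a) & (model.residue_number <= b)
    disp = np.zeros_like(model.xyz)
    disp[mask] = rng.normal(size=(int(mask.sum()), 3))
    disp[mask] -= disp[mask].mean(axis=0)
    base = model.xyz[helix]
    for _ in range(12):
        _, fitted = kabsch_fit(base + disp[helix], base)
        if fitted <= 0 or abs(fitted - target_rmsd) < 1e-9 * max(target_rmsd, 1.0):
            break
        disp *= target_rmsd / fitted
    field[mask] = disp[mask]
    return field


def state_templates(receptor: StructureModel,
                    spec: SyntheticSpec) -> list[np.ndarray]:
    """Noise-free coordinates of each state (domain offsets + TM distortion).

    Deterministic under ``spec.seed``: per-state random fields come from
    spawned child streams of the spec seed.
    """
    children = np.random.SeedSequence(spec.seed).spawn(len(spec.states) + 1)
    templates = []
    for state, ss in zip(spec.states, children[:-1]):
        coords = receptor.xyz.copy()
        for domain, offset in state.anchor_offsets.items():
            coords[_domain_mask(receptor, domain)] += np.asarray(offset, dtype=float)
        coords += _tm_perturbation_field(receptor, state.tm_perturbation_rmsd,
                                         np.random.default_rng(ss))
        templates.append(coords)
    return templates


def simulate_state_path(spec: SyntheticSpec, n_frames: int | None = None,
                        rng: np.random.Generator | None = None) -> np.ndarray:
    """Hidden Markov state path (integer labels) under the transition model."""
    n = spec.n_frames if n_frames is None else int(n_frames)
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(spec.seed).spawn(
            len(spec.states) + 1)[-1])
    k = len(spec.states)
    labels = np.empty(n, dtype=int)
    labels[0] = 0
    cum = np.cumsum(spec.transition, axis=1)
    draws = rng.random(n)
    for f in range(1, n):
        labels[f] = int(np.searchsorted(cum[labels[f - 1]], draws[f]))
    return labels


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation from a normalised Gaussian quaternion."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def generate_trajectory(receptor: StructureModel, spec: SyntheticSpec,
                        ) -> tuple[TrajectoryEnsemble, np.ndarray]:
    """Labelled multi-state trajectory of the toy receptor.

    Each frame is the current state's template plus isotropic Gaussian
    noise of ``spec.noise_sigma``; when ``spec.rigid_jitter`` is on, a
    uniform random rotation and a uniform translation (up to
    ``spec.jitter_translation`` per axis) are applied to the whole frame.
    Returns the ensemble and the per-frame ground-truth state labels.
    Bit-identical under the same seed.
    """
    templates = state_templates(receptor, spec)
    labels = simulate_state_path(spec)
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed).spawn(
        len(spec.states) + 2)[-1])
    coords = np.empty((spec.n_frames, receptor.n_atoms, 3))
    for f in range(spec.n_frames):
        frame = templates[labels[f]] + rng.normal(scale=spec.noise_sigma,
                                                  size=(receptor.n_atoms, 3))
        if spec.rigid_jitter:
            R = _random_rotation(rng)
            t = rng.uniform(-spec.jitter_translation, spec.jitter_translation, 3)
            frame = frame @ R.T + t
        coords[f] = frame
    times = np.arange(spec.n_frames) * spec.frame_interval_ps
    traj = TrajectoryEnsemble(coordinates=coords, times=times,
                              atom_table=receptor)
    return traj, labels


def ground_truth_distance_series(receptor: StructureModel, spec: SyntheticSpec,
                                 labels: np.ndarray, anchors) -> "pd.DataFrame":
    """Noise-free anchor distances per frame implied by the state path.

    This is the imposed signal that :func:`confland.reaction_coordinates.
    domain_distances` should recover from the noisy trajectory.
    """
    from .reaction_coordinates import domain_distances

    templates = state_templates(receptor, spec)
    per_state = []
    for coords in templates:
        series = domain_distances(receptor.with_coordinates(coords), anchors)
        per_state.append((series.lrr_hr[0], series.lrr_tm[0], series.tm_hr[0]))
    per_state = np.asarray(per_state)
    lab = np.asarray(labels, dtype=int)
    return pd.DataFrame({"frame": np.arange(lab.size),
                         "state": lab,
                         "lrr_hr_A": per_state[lab, 0],
                         "lrr_tm_A": per_state[lab, 1],
                         "tm_hr_A": per_state[lab, 2]})


def apply_exact_kink(receptor: StructureModel, kink_spec,
                     angle_deg: float) -> StructureModel:
    """Place the four kink Calphas so the kink angle is exactly ``angle_deg``.

    The lower-pair axis is set along +z and the upper-pair axis rotated by
    the requested angle about x; all other atoms are untouched. Used to
    validate angle recovery analytically.
    """
    a = np.deg2rad(angle_deg)
    upper_dir = np.array([0.0, np.sin(a), np.cos(a)])
    coords = receptor.xyz.copy()

    def idx(resid: int) -> int:
        hit = np.nonzero((receptor.residue_number == resid)
                         & (receptor.atom_name == "CA"))[0]
        return int(hit[0])

    coords[idx(kink_spec.lower_pair[1][1])] = [0.0, 0.0, 0.0]
    coords[idx(kink_spec.lower_pair[0][1])] = [0.0, 0.0, 6.0]
    coords[idx(kink_spec.upper_pair[1][1])] = [0.0, 0.0, 7.0]
    coords[idx(kink_spec.upper_pair[0][1])] = (np.array([0.0, 0.0, 7.0])
                                               + 5.0 * upper_dir)
    return receptor.with_coordinates(coords)


# ---------------------------------------------------------------------------
# membrane box
# ---------------------------------------------------------------------------

def generate_membrane_box(n_lipid_sites: int = 3000, n_water: int = 3000,
                          box: tuple[float, float, float] = (60.0, 60.0, 84.0),
                          seed: int = 0, n_frames: int = 1,
                          ) -> tuple[StructureModel, TrajectoryEnsemble]:
    """Slab-structured pseudo-membrane: tails |z|<15, phosphate shells at
    |z|~19, water |z|>21, uniform in xy.

    Atom names (CT1 tails, P phosphate, OH2 water) match the default group
    dictionary of :mod:`confland.membrane_profile`. Extra frames (``n_frames``
    > 1) add a small positional jitter. The box must be tall enough for the
    water layers (z edge > 42 A).
    """
    bx, by, bz = (float(v) for v in box)
    if bz / 2.0 <= 21.0:
        raise ValueError("box z edge must exceed 42 A to fit the water layers")
    rng = np.random.default_rng(seed)
    n_phos = max(2, n_lipid_sites // 10)
    n_tail = n_lipid_sites - n_phos

    def uniform_xy(n: int) -> np.ndarray:
        return np.column_stack([rng.uniform(0, bx, n), rng.uniform(0, by, n)])

    tail_z = rng.uniform(-15.0, 15.0, n_tail)
    half = n_phos // 2
    phos_z = np.concatenate([
        np.clip(19.0 + rng.normal(0.0, 0.8, half), 16.0, 20.9),
        np.clip(-19.0 + rng.normal(0.0, 0.8, n_phos - half), -20.9, -16.0)])
    half_w = n_water // 2
    water_z = np.concatenate([rng.uniform(21.0, bz / 2.0, half_w),
                              rng.uniform(-bz / 2.0, -21.0, n_water - half_w)])

    names = np.concatenate([np.full(n_tail, "CT1"), np.full(n_phos, "P"),
                            np.full(n_water, "OH2")])
    elements = np.concatenate([np.full(n_tail, "C"), np.full(n_phos, "P"),
                               np.full(n_water, "O")])
    resnames = np.concatenate([np.full(n_tail + n_phos, "SDPC"),
                               np.full(n_water, "TIP3")])
    masses = np.concatenate([np.full(n_tail, 12.011), np.full(n_phos, 30.974),
                             np.full(n_water, 15.999)])
    n_atoms = n_tail + n_phos + n_water
    xyz = np.column_stack([
        np.vstack([uniform_xy(n_tail), uniform_xy(n_phos), uniform_xy(n_water)]),
        np.concatenate([tail_z, phos_z, water_z])])
    model = StructureModel(
        serial=np.arange(1, n_atoms + 1),
        atom_name=names, element=elements,
        residue_number=np.arange(1, n_atoms + 1),
        residue_name=resnames,
        chain_id=np.concatenate([np.full(n_tail + n_phos, "M"),
                                 np.full(n_water, "W")]),
        xyz=xyz, mass=masses)
    frames = [xyz]
    for _ in range(n_frames - 1):
        frames.append(xyz + rng.normal(scale=0.3, size=xyz.shape))
    traj = TrajectoryEnsemble(
        coordinates=np.stack(frames),
        times=np.arange(n_frames) * 10.0,
        atom_table=model,
        box=np.tile([bx, by, bz], (n_frames, 1)))
    return model, traj


# ---------------------------------------------------------------------------
# fixtures on disk
# ---------------------------------------------------------------------------

def write_fixture_set(out_dir: str | Path, receptor: StructureModel,
                      traj: TrajectoryEnsemble, labels: np.ndarray,
                      traj_format: str = "dcd") -> dict[str, Path]:
    """Write receptor PDB + trajectory (DCD or multi-model PDB) + truth CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {"structure": out / "receptor.pdb",
             "trajectory": out / f"trajectory.{'pdb' if traj_format == 'multi-pdb' else traj_format}",
             "truth": out / "state_labels.csv"}
    write_pdb(receptor, paths["structure"])
    write_trajectory(traj, paths["trajectory"], fmt=traj_format)
    pd.DataFrame({"frame": np.arange(traj.n_frames),
                  "time_ps": traj.times,
                  "state_label": np.asarray(labels, dtype=int)}
                 ).to_csv(paths["truth"], index=False)
    return paths
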