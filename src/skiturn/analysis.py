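"""Evaluation metrics, EMG processing and the end-to-end pipeline.

Metrics mirror the study protocol: per-channel RMSD between simulated and
reference kinematics, the skier's track (ankle-joint-center paths of outside
and inside leg projected onto the slope), COM speed, and the minimum turn
radius from the curvature of the smoothed track.  EMG envelopes are obtained
by full-wave rectification and a zero-lag second-order dual-pass Butterworth
low-pass at 6 Hz, then scaled to the maximum of the estimated activation for
comparison.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal
from scipy.interpolate import make_interp_spline

from .dynamics import SkierSystem, Trajectory


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline failed at stage {stage!r}: {cause}")
        self.stage = stage
        self.cause = cause


def rmsd(series_a, series_b) -> float:
    """Root mean squared difference of two equal-length series."""
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    if a.shape != b.shape or a.size < 1:
        raise ValueError("series must have identical nonzero length")
    return float(np.sqrt(np.mean((a - b) ** 2)))


def pearson(a, b) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.std() == 0 or b.std() == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def _curvature(t, x, y, smooth: float = 0.0):
    """Signed curvature of a planar path via spline derivatives."""
    k = min(5, len(t) - 1)
    sx = make_interp_spline(t, x, k=k)
    sy = make_interp_spline(t, y, k=k)
    x1, x2 = sx(t, 1), sx(t, 2)
    y1, y2 = sy(t, 1), sy(t, 2)
    denom = (x1**2 + y1**2) ** 1.5
    with np.errstate(divide="ignore", invalid="ignore"):
        return (x1 * y2 - y1 * x2) / denom


def track_metrics(system: SkierSystem, traj: Trajectory, overlay=None,
                  steering_only: bool = True) -> dict:
    """Per-leg track, COM speed and minimum turn radius.

    The track is the ankle-joint-center path in course coordinates: downhill
    progression from the planar dynamics, transverse offset from the turn
    overlay (if given).  Radius is 1/curvature of the smoothed track; for a
    straight schuss (curvature ~ 0) no radius is reported.
    """
    q, qd, *_ = system.split(traj.states)
    kin = system.plane.kinematics(q, qd)
    m_tot = system.plane.total_mass
    com_v = sum(b.mass * np.asarray(system.plane.point_state(kin, b.name, b.com_offset)[1])
                for b in system.plane.bodies) / m_tot
    speed = np.hypot(com_v[:, 0], com_v[:, 1])
    tracks = {}
    if overlay is not None:
        psi, y_lat = overlay.lateral_path(traj.times, speed)
    else:
        y_lat = np.zeros_like(traj.times)
    for leg, side, sign in (("outside", "r", +1), ("inside", "l", -1)):
        p_ank, _, _ = system.plane.point_state(kin, f"tibia_{side}", [0.0, -0.43])
        # downhill arc-length coordinate along the slope
        s_down = p_ank[:, 0] / np.cos(system.slope_angle)
        y = y_lat + sign * 0.15          # stance width offset
        tracks[leg] = np.stack([s_down, y], axis=1)
    out = {"speed": speed, "tracks": tracks}
    curv = _curvature(traj.times, tracks["outside"][:, 0], tracks["outside"][:, 1])
    if overlay is not None and steering_only:
        mask = overlay.edging(traj.times) > np.deg2rad(3.0)
    else:
        mask = np.ones_like(traj.times, dtype=bool)
    curv_sel = np.abs(curv[mask]) if mask.any() else np.array([])
    if curv_sel.size and curv_sel.max() > 1e-4:
        out["min_turn_radius"] = float(1.0 / curv_sel.max())
    else:
        out["min_turn_radius"] = None
    return out


def emg_envelope(raw, fs: float, cutoff: float = 6.0) -> np.ndarray:
    """Full-wave rectified, zero-lag 2nd-order dual-pass low-pass envelope."""
    if fs <= 2 * cutoff:
        raise ValueError("sampling rate must exceed twice the cutoff")
    b, a = signal.butter(2, cutoff / (fs / 2.0))
    return signal.filtfilt(b, a, np.abs(np.asarray(raw, dtype=float)))


def compare_activations(estimated: pd.DataFrame, emg: pd.DataFrame,
                        mapping: dict[str, str] | None = None) -> pd.DataFrame:
    """Scale each EMG channel to the maximum of the matching estimated
    activation (EMG amplitude is scale-free) and report Pearson correlations.

    ``mapping``: EMG channel -> activation column; defaults to same-name
    matching.  All-zero estimated channels are skipped with a note.
    """
    from .synthetic import EMG_MUSCLE_MAP

    if mapping is None:
        mapping = {c: (c if c in estimated.columns else EMG_MUSCLE_MAP.get(c, c))
                   for c in emg.columns if c != "time"}
    t_est = estimated["time"].to_numpy()
    t_emg = emg["time"].to_numpy()
    rows = []
    for emg_name, act_name in mapping.items():
        if act_name not in estimated.columns:
            raise ValueError(f"no estimated channel {act_name!r} for EMG {emg_name!r}")
        act = estimated[act_name].to_numpy()
        env = np.interp(t_est, t_emg, emg[emg_name].to_numpy())
        if np.max(act) <= 0:
            rows.append({"emg": emg_name, "muscle": act_name, "scale": np.nan,
                         "correlation": np.nan, "note": "estimated channel all zero"})
            continue
        scale = np.max(act) / max(np.max(env), 1e-12)
        rows.append({"emg": emg_name, "muscle": act_name, "scale": scale,
                     "correlation": pearson(env, act), "note": ""})
    return pd.DataFrame(rows)


@dataclass
class EvaluationReport:
    channel_rmsd: dict[str, float]          # deg for angles, m for translations
    max_angle_rmsd_deg: float
    track_rmsd: dict[str, float]            # m per leg (vs reference track)
    mean_speed: float                       # m/s
    min_turn_radius: float | None           # m
    peak_activations: dict[str, float]
    peak_acl: dict[str, float]              # N per leg
    peak_acl_bw: dict[str, float]
    objective: float
    objective_parts: dict[str, float]
    solver_status: str
    emg_correlations: dict[str, float] = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)

    def to_json(self, path: str | Path):
        Path(path).write_text(json.dumps(asdict(self), indent=2, default=float))


def evaluate_solution(system: SkierSystem, sol, ref, fixture=None,
                      overlay=None, coeffs=None) -> EvaluationReport:
    """Compute the full evaluation report for a tracking solution."""
    from .knee_acl import knee_pipeline
    from .tracking import ReferenceData

    assert isinstance(ref, ReferenceData)
    traj = sol.trajectory()
    refv = ref.resampled(traj.times)
    names = ref.tracked
    ch_rmsd = {}
    max_ang = 0.0
    for i, c in enumerate(names):
        r = rmsd(sol.states[:, system.plane.coord_index(c)], refv[:, i])
        if c in ("pelvis_x", "pelvis_z"):
            ch_rmsd[c] = r
        else:
            ch_rmsd[c] = float(np.rad2deg(r))
            max_ang = max(max_ang, ch_rmsd[c])
    overlay = overlay or (fixture.overlay if fixture is not None else None)
    tm = track_metrics(system, traj, overlay=overlay)
    track_rmsd = {}
    if fixture is not None:
        tm_ref = track_metrics(system, fixture.trajectory, overlay=overlay)
        for leg in ("outside", "inside"):
            n = min(len(tm["tracks"][leg]), len(tm_ref["tracks"][leg]))
            d = tm["tracks"][leg][:n] - tm_ref["tracks"][leg][:n]
            track_rmsd[leg] = float(np.sqrt(np.mean(np.sum(d**2, axis=1))))
    a = sol.states[:, 2 * system.n_q + system.n_m:2 * system.n_q + 2 * system.n_m]
    peak_act = {m: float(a[:, i].max()) for i, m in enumerate(system.muscles.names)}
    peak_acl, peak_acl_bw = {}, {}
    if overlay is not None:
        mass = system.config.get("subject", {}).get("mass_kg", 72.0)
        for leg in ("right", "left"):
            acl = knee_pipeline(system, traj, overlay, leg=leg, coeffs=coeffs)
            peak_acl[leg] = float(acl["total"].max())
            peak_acl_bw[leg] = peak_acl[leg] / (mass * 9.81)
    emg_corr = {}
    if fixture is not None:
        est = pd.DataFrame(a, columns=system.muscles.names)
        est.insert(0, "time", traj.times)
        cmp_df = compare_activations(est, fixture.emg)
        emg_corr = dict(zip(cmp_df["emg"], cmp_df["correlation"]))
    return EvaluationReport(
        channel_rmsd=ch_rmsd, max_angle_rmsd_deg=max_ang, track_rmsd=track_rmsd,
        mean_speed=float(np.mean(tm["speed"])), min_turn_radius=tm["min_turn_radius"],
        peak_activations=peak_act, peak_acl=peak_acl, peak_acl_bw=peak_acl_bw,
        objective=sol.objective,
        objective_parts={"tracking": sol.tracking_part, "effort": sol.effort_part,
                         "regularization": sol.regularization_part},
        solver_status=sol.status, emg_correlations=emg_corr)


def run_pipeline(config: dict | None = None, seed: int = 0,
                 out_dir: str | Path | None = None) -> EvaluationReport:
    """End-to-end run: fixture -> guess -> solve -> knee/ACL -> metrics.

    ``config`` keys (all optional): ``model`` (preset name or dict),
    ``weights`` {w1,w2,w3}, ``effort_exponent``, ``n_mesh``, ``T``,
    ``guess`` ('schuss'|'pd_tracking'), ``acl_coefficients`` (path/preset),
    solver settings under ``solver``.  Stage failures raise
    :class:`PipelineStageError` naming the stage.
    """
    from . import tracking as trk
    from .knee_acl import KneeModelCoefficients
    from .synthetic import generate_reference_turn

    cfg = config or {}

    def stage(name, fn):
        try:
            return fn()
        except Exception as exc:
            raise PipelineStageError(name, exc) from exc

    system = stage("model", lambda: SkierSystem(cfg.get("model", "reduced_planar")))
    fixture = stage("reference", lambda: generate_reference_turn(
        system, seed=seed, n_mesh=cfg.get("n_mesh", 75), T=cfg.get("T", 2.0)))
    coeffs = stage("acl_coefficients", lambda: KneeModelCoefficients.from_config(
        cfg.get("acl_coefficients")))
    w = cfg.get("weights", {})
    spec = trk.ObjectiveSpec(w1=w.get("w1", 1.0), w2=w.get("w2", 10.0),
                             w3=w.get("w3", 1e-3),
                             effort_exponent=cfg.get("effort_exponent", 2.0))
    grid = trk.CollocationGrid(n_mesh=cfg.get("n_mesh", 75), T=cfg.get("T", 2.0))
    ref = trk.ReferenceData.from_fixture(fixture, system)
    problem = stage("assemble", lambda: trk.assemble_nlp(system, ref, spec=spec, grid=grid))
    z0 = stage("initial_guess", lambda: trk.make_initial_guess(
        cfg.get("guess", "schuss"), problem))
    sol = stage("solve", lambda: trk.solve_tracking(problem, z0,
                                                    **cfg.get("solver", {})))
    report = stage("evaluate", lambda: evaluate_solution(
        system, sol, ref, fixture=fixture, coeffs=coeffs))
    report.manifest = {"seed": seed, "config": {k: v for k, v in cfg.items()
                                                if k != "model"},
                       **fixture.manifest}
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        report.to_json(out / "report.json")
        write_trajectory_table(sol.trajectory(), system, out / "solution.csv")
        write_trajectory_table(fixture.trajectory, system, out / "reference.csv")
    return report


def write_trajectory_table(traj: Trajectory, system: SkierSystem, path: str | Path):
    """Delimited export with explicit units in the headers (angles in deg)."""
    cols = {"time [s]": traj.times}
    for j, n in enumerate(system.plane.coordinate_names):
        if n in ("pelvis_x", "pelvis_z"):
            cols[f"{n} [m]"] = traj.states[:, j]
        else:
            cols[f"{n} [deg]"] = np.rad2deg(traj.states[:, j])
    q, qd, s, a, mem = system.split(traj.states)
    for i, m in enumerate(system.muscles.names):
        cols[f"a_{m} [-]"] = a[:, i]
        cols[f"u_{m} [-]"] = traj.controls[:, i]
    pd.DataFrame(cols).to_csv(path, index=False)


def load_trajectory_table(path: str | Path, system: SkierSystem) -> pd.DataFrame:
    df = pd.read_csv(path)
    out = pd.DataFrame({"time": df["time [s]"]})
    for col in df.columns:
        if col == "time [s]":
            continue
        name, unit = col.rsplit(" [", 1)
        vals = df[col].to_numpy()
        out[name] = np.deg2rad(vals) if unit.startswith("deg") else vals
    return out
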