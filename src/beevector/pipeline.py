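"""End-to-end orchestration and summary statistics.

Runs simulate (or ingest) -> track -> boundary angles -> exclusions ->
circular summaries -> hypothesis tests -> report.  Summaries mirror the
analysis structure of the detour experiment: signed errors against the
geometric target at each boundary, cells of role x detour angle x
boundary, per-individual repeatability, and a least-squares estimate of
the point the bearing lines converge on (the inferred navigational
goal).
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .circstats import CircularSample, circ_mean_resultant, circ_sd, mww_test
from .geometry import DetourConfig, bearing_resume_turn, shortcut_turn, wrap_angle
from .synthetic import FlightGenParams, gen_cohort
from .tracking import BearingRecord, apply_exclusions, boundary_angles

__all__ = [
    "RunManifest",
    "signed_error",
    "summarize_boundaries",
    "progressive_shift",
    "individual_repeatability",
    "goal_convergence",
    "run_pipeline",
    "records_to_frame",
]

BOUNDARY_IDS = ("r1", "r2", "r3", "last_visible")


def signed_error(angle, target):
    """Signed angular error: wrap(angle - target), degrees.

    Positive means the bee deviated to the *left* of the target
    (counterclockwise), negative to the right.
    """
    return wrap_angle(np.asarray(angle, float) - np.asarray(target, float))


def records_to_frame(records, meta: pd.DataFrame = None) -> pd.DataFrame:
    """Flatten BearingRecords (optionally joined to cohort metadata)."""
    df = pd.DataFrame([r.to_dict() for r in records])
    if meta is not None:
        df = df.merge(meta, on="bee_id", how="left", suffixes=("", "_meta"))
    return df


def summarize_boundaries(df: pd.DataFrame, by=("role", "detour_angle_deg"),
                         cfg: DetourConfig = None) -> pd.DataFrame:
    """Circular mean +/- s.d. of signed errors per cell and boundary.

    ``df`` is a flat record table (see :func:`records_to_frame`) with
    ``error_at_r1..r3`` and ``error_last_visible`` columns.  Empty
    cells are omitted with a warning.  When a config is given, both
    competing target predictions (shortcut and bearing-resume) are
    attached per detour angle.
    """
    err_cols = ["error_at_r1", "error_at_r2", "error_at_r3",
                "error_last_visible"]
    rows = []
    group_iter = df.groupby(list(by)) if by else [((), df)]
    for key, cell in group_iter:
        if not isinstance(key, tuple):
            key = (key,)
        for bid, col in zip(BOUNDARY_IDS, err_cols):
            vals = cell[col].to_numpy(dtype=float)
            vals = vals[np.isfinite(vals)]
            if vals.size == 0:
                warnings.warn(f"empty cell {key}/{bid}: omitted")
                continue
            mu, r = circ_mean_resultant(vals)
            row = dict(zip(by, key))
            row.update({"boundary": bid, "n": int(vals.size),
                        "mean_error_deg": mu,
                        "circ_sd_deg": circ_sd(r) if r > 0 else float("inf")})
            rows.append(row)
    out = pd.DataFrame(rows)
    if cfg is not None and "detour_angle_deg" in out.columns:
        preds = {}
        for ang in out["detour_angle_deg"].unique():
            sub = replace(cfg, detour_relative_angle=float(ang))
            preds[ang] = (shortcut_turn(sub), bearing_resume_turn(sub))
        out["target_shortcut_deg"] = out["detour_angle_deg"].map(
            lambda a: preds[a][0])
        out["target_resume_deg"] = out["detour_angle_deg"].map(
            lambda a: preds[a][1])
    return out


def progressive_shift(df: pd.DataFrame) -> pd.DataFrame:
    """Pooled-reflected per-boundary mean errors on complete cases.

    Mirrored detour conditions carry lag errors of opposite sign, so a
    naive pool across conditions cancels the corrective-turn signature.
    Here errors from conditions with a positive target are reflected
    (negated) before pooling, and only bees observed at *all four*
    boundaries contribute, so consecutive boundaries compare the same
    animals.  A population correcting toward the target shows
    |mean_error| shrinking monotonically from the first boundary to the
    last visible position.
    """
    cols = ["error_at_r1", "error_at_r2", "error_at_r3",
            "error_last_visible"]
    cc = df[np.isfinite(df[cols].to_numpy(dtype=float)).all(axis=1)]
    if len(cc) == 0:
        return pd.DataFrame(columns=["boundary", "n", "mean_error_deg"])
    sign = np.where(cc["target_angle_deg"].to_numpy(dtype=float) > 0,
                    -1.0, 1.0)
    rows = []
    for bid, col in zip(BOUNDARY_IDS, cols):
        mu, _ = circ_mean_resultant(cc[col].to_numpy(dtype=float) * sign)
        rows.append({"boundary": bid, "n": int(len(cc)),
                     "mean_error_deg": mu})
    return pd.DataFrame(rows)


def individual_repeatability(df: pd.DataFrame,
                             error_col: str = "error_last_visible") -> tuple:
    """Per-bee circular summaries for repeatedly tested individuals.

    Bees with fewer than two retained records are excluded from this
    analysis.  Returns ``(per_bee DataFrame, spread_ratio)`` where
    ``spread_ratio`` is the median individual circular s.d. divided by
    the pooled circular s.d. — values well below 1 indicate individuals
    are more consistent than the population scatter suggests.
    """
    per_bee = []
    pooled = df[error_col].to_numpy(dtype=float)
    pooled = pooled[np.isfinite(pooled)]
    for bee, sub in df.groupby("bee_id"):
        vals = sub[error_col].to_numpy(dtype=float)
        vals = vals[np.isfinite(vals)]
        if vals.size < 2:
            continue
        mu, r = circ_mean_resultant(vals)
        sd = 0.0 if r > 1 - 1e-12 else circ_sd(r)
        per_bee.append({"bee_id": bee, "n": int(vals.size),
                        "mean_error_deg": mu, "circ_sd_deg": sd})
    per_bee = pd.DataFrame(per_bee)
    if len(per_bee) == 0 or pooled.size < 2:
        return per_bee, float("nan")
    _, r_pool = circ_mean_resultant(pooled)
    pooled_sd = circ_sd(r_pool)
    ratio = float(per_bee["circ_sd_deg"].median() / pooled_sd) \
        if pooled_sd > 0 else float("nan")
    return per_bee, ratio


def goal_convergence(lines) -> tuple:
    """Least-squares intersection of bearing lines.

    ``lines`` is an iterable of ``((x0, y0), bearing_deg)`` — a point
    each line passes through (a detour exit) and its direction (CCW
    from +x).  Returns ``(point, rms_residual)`` for the point
    minimising the summed squared perpendicular distances, from the
    closed-form normal equations.  All-parallel lines have no unique
    minimiser and raise ``ValueError``.
    """
    lines = list(lines)
    if len(lines) < 2:
        raise ValueError("need at least two lines")
    A = np.zeros((2, 2))
    b = np.zeros(2)
    ps, ds = [], []
    for (x0, y0), bearing in lines:
        th = np.radians(float(bearing))
        d = np.array([np.cos(th), np.sin(th)])
        p = np.array([x0, y0], dtype=float)
        proj = np.eye(2) - np.outer(d, d)  # perpendicular projector
        A += proj
        b += proj @ p
        ps.append(p)
        ds.append(d)
    if np.linalg.cond(A) > 1e10:
        raise ValueError("lines are (nearly) all parallel: no unique "
                         "convergence point; only a direction is constrained")
    q = np.linalg.solve(A, b)
    sq = 0.0
    for p, d in zip(ps, ds):
        v = q - p
        sq += float(v @ v - (v @ d) ** 2)
    rms = float(np.sqrt(max(sq, 0.0) / len(lines)))
    from .geometry import Point2D
    return Point2D(float(q[0]), float(q[1])), rms


# --------------------------------------------------------------------------
# Orchestration
# --------------------------------------------------------------------------

@dataclass
class RunManifest:
    """Everything a pipeline run needs, recorded for reproducibility."""

    config: DetourConfig = field(default_factory=DetourConfig)
    flight_params: FlightGenParams = field(default_factory=FlightGenParams)
    n_bees: int = 50
    seed: int = 0
    exclusion_fraction: float = 0.0
    recruit_fraction: float = 0.5
    aim: str = "shortcut"
    output_dir: str = "beevector_out"
    make_figures: bool = False

    @classmethod
    def from_yaml(cls, path) -> "RunManifest":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = DetourConfig(**raw.pop("config", {}))
        fp = FlightGenParams(**raw.pop("flight_params", {}))
        return cls(config=cfg, flight_params=fp, **raw)

    def content_hash(self) -> str:
        blob = json.dumps({
            "config": {k: getattr(self.config, k)
                       for k in self.config.__dataclass_fields__},
            "flight_params": {k: getattr(self.flight_params, k)
                              for k in self.flight_params.__dataclass_fields__},
            "n_bees": self.n_bees, "seed": self.seed,
            "exclusion_fraction": self.exclusion_fraction,
            "recruit_fraction": self.recruit_fraction, "aim": self.aim,
        }, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(manifest: RunManifest) -> dict:
    """Simulate a cohort and run the full analysis; write the bundle.

    Stages: generate cohort -> boundary angles -> exclusion filter ->
    per-cell circular summaries -> Mardia-Watson-Wheeler across detour
    conditions -> report files.  Deterministic for a fixed manifest:
    re-running writes byte-identical summary CSVs.

    Returns a dict with the in-memory tables and writes
    ``summaries/*.csv``, ``stats/*.json`` and ``manifest.lock.yaml``
    under ``manifest.output_dir``.
    """
    out = Path(manifest.output_dir)
    (out / "summaries").mkdir(parents=True, exist_ok=True)
    (out / "stats").mkdir(exist_ok=True)

    meta, trajs = gen_cohort(manifest.config, manifest.flight_params,
                             manifest.n_bees, seed=manifest.seed,
                             exclusion_fraction=manifest.exclusion_fraction,
                             recruit_fraction=manifest.recruit_fraction,
                             aim=manifest.aim)
    records = []
    for _, row in meta.iterrows():
        rec = boundary_angles(trajs[row.bee_id],
                              radii=manifest.config.boundary_radii,
                              target_angle=row.target_angle_deg,
                              exit_duration=row.exit_duration_s)
        rec.stopped = bool(row.stopped)
        records.append(rec)

    if not records:
        report = {"n_input": 0, "note": "no data"}
        (out / "stats" / "report.json").write_text(json.dumps(report, indent=2))
        return {"records": [], "summary": pd.DataFrame(), "report": report}

    retained, excluded = apply_exclusions(records)
    df_all = records_to_frame(records, meta)
    df_ret = df_all[~df_all["excluded"]].copy()

    summary = summarize_boundaries(df_ret, cfg=manifest.config) \
        if len(df_ret) else pd.DataFrame()
    pooled = summarize_boundaries(df_ret, by=("role",), cfg=None) \
        if len(df_ret) else pd.DataFrame()
    per_bee, spread_ratio = individual_repeatability(df_ret) \
        if len(df_ret) else (pd.DataFrame(), float("nan"))
    shift = progressive_shift(df_ret) if len(df_ret) else pd.DataFrame()

    stats_out = {}
    if len(df_ret):
        groups = [CircularSample(s["error_last_visible"].dropna().to_numpy(),
                                 str(k))
                  for k, s in df_ret.groupby("detour_angle_deg")
                  if s["error_last_visible"].notna().sum() >= 2]
        if len(groups) >= 2:
            stats_out["mww_across_detours"] = mww_test(groups).to_dict()

    df_all.to_csv(out / "summaries" / "records.csv", index=False)
    summary.to_csv(out / "summaries" / "boundary_summary.csv", index=False)
    pooled.to_csv(out / "summaries" / "pooled_by_role.csv", index=False)
    per_bee.to_csv(out / "summaries" / "per_bee.csv", index=False)
    shift.to_csv(out / "summaries" / "progressive_shift.csv", index=False)

    report = {
        "n_input": len(records),
        "n_retained": len(retained),
        "n_excluded": len(excluded),
        "spread_ratio": spread_ratio,
        "tests": stats_out,
        "config_hash": manifest.content_hash(),
        "seed": manifest.seed,
    }
    (out / "stats" / "report.json").write_text(
        json.dumps(report, indent=2, default=float))
    lock = {"config_hash": manifest.content_hash(), "seed": manifest.seed,
            "n_bees": manifest.n_bees}
    with open(out / "manifest.lock.yaml", "w") as fh:
        yaml.safe_dump(lock, fh, sort_keys=False)

    if manifest.make_figures:
        _polar_figures(df_ret, out / "figures")

    return {"records": records, "meta": meta, "summary": summary,
            "pooled": pooled, "per_bee": per_bee,
            "progressive_shift": shift, "report": report}


def _polar_figures(df: pd.DataFrame, figdir: Path) -> None:
    """One polar histogram of signed errors per boundary."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    figdir.mkdir(parents=True, exist_ok=True)
    cols = {"r1": "error_at_r1", "r2": "error_at_r2",
            "r3": "error_at_r3", "last_visible": "error_last_visible"}
    for bid, col in cols.items():
        vals = df[col].to_numpy(dtype=float)
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            continue
        fig = plt.figure(figsize=(4, 4))
        ax = fig.add_subplot(projection="polar")
        ax.set_theta_zero_location("N")
        ax.hist(np.radians(vals), bins=36)
        ax.set_title(f"signed error at {bid} (n={vals.size})")
        fig.savefig(figdir / f"errors_{bid}.png", dpi=100)
        plt.close(fig)
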