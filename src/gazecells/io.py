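"""Session bundles: CSV readers/writers, validation, and the pipeline driver.

A session bundle is a directory holding one synthetic session as plain
CSV/YAML files plus a ``bundle.yaml`` manifest with the file paths and the
session metadata (bird id, hemisphere, task variant, seed). All CSVs are
UTF-8, comma-separated with a mandatory header row, and every file written
by this package starts with a provenance comment line carrying the config
hash and the seed.

Units at every interface: seconds from session start, millimeters,
degrees. (Radians appear only inside geometry code.)
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .behavior import BehaviorTrace, TaskEvents, generate_session
from .config import (
    ArenaConfig,
    BehaviorConfig,
    EyeCalibration,
    TaskConfig,
    load_configs,
    save_configs,
)
from .spikes import (
    WAVEFORM_SAMPLES,
    contralateral_eye,
    default_population,
    generate_spike_population,
)

log = logging.getLogger("gazecells")

TRACE_COLUMNS = ["t", "x", "y", "z", "qw", "qx", "qy", "qz", "light"]
SPIKE_COLUMNS = ["cell_id", "t"]
HEMISPHERES = ("left", "right")


class SchemaError(ValueError):
    """A file failed validation; the message names file, row and column."""


@dataclass
class SessionBundle:
    """Manifest of one session: file paths plus session metadata."""

    root: Path
    trace: Path
    events: Path
    spikes: Path
    waveforms: Path
    cells: Path
    configs: Path
    bird_id: str
    hemisphere: str
    task_variant: str
    seed: int

    @classmethod
    def from_yaml(cls, path) -> "SessionBundle":
        path = Path(path)
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        meta = doc.get("metadata", {})
        if "hemisphere" not in meta:
            raise SchemaError(
                f"{path}: metadata lacks 'hemisphere'; contra/ipsi undefined"
            )
        if meta["hemisphere"] not in HEMISPHERES:
            raise SchemaError(
                f"{path}: metadata.hemisphere must be one of {HEMISPHERES}"
            )
        root = path.parent
        paths = doc.get("paths", {})
        try:
            return cls(
                root=root,
                trace=root / paths["trace"],
                events=root / paths["events"],
                spikes=root / paths["spikes"],
                waveforms=root / paths["waveforms"],
                cells=root / paths["cells"],
                configs=root / paths["configs"],
                bird_id=str(meta.get("bird_id", "synthetic")),
                hemisphere=meta["hemisphere"],
                task_variant=str(meta.get("task_variant", "random")),
                seed=int(meta.get("seed", 0)),
            )
        except KeyError as exc:
            raise SchemaError(f"{path}: paths lacks entry {exc}") from exc

    def to_yaml(self, path) -> None:
        doc = {
            "paths": {
                k: str(getattr(self, k).name)
                for k in ("trace", "events", "spikes", "waveforms", "cells", "configs")
            },
            "metadata": {
                "bird_id": self.bird_id,
                "hemisphere": self.hemisphere,
                "task_variant": self.task_variant,
                "seed": self.seed,
            },
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=True)


@dataclass
class Session:
    """A validated in-memory session."""

    trace: BehaviorTrace
    light_state: np.ndarray
    trials: pd.DataFrame
    spikes: pd.DataFrame
    waveforms: np.ndarray  # (n_cells, WAVEFORM_SAMPLES) ordered by cell id
    cells: pd.DataFrame
    arena: ArenaConfig
    behavior: BehaviorConfig
    task: TaskConfig
    calibration: EyeCalibration
    bundle: SessionBundle


def config_hash(*configs, extra: Optional[dict] = None) -> str:
    """Short stable hash of dataclass configs plus free-form parameters."""
    doc = {}
    for cfg in configs:
        doc[type(cfg).__name__] = {
            f.name: _plain(getattr(cfg, f.name)) for f in dataclasses.fields(cfg)
        }
    if extra:
        doc["extra"] = {k: _plain(v) for k, v in sorted(extra.items())}
    blob = yaml.safe_dump(doc, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _plain(v):
    if isinstance(v, np.ndarray):
        return v.tolist()
    if isinstance(v, (np.floating, np.integer)):
        return v.item()
    if isinstance(v, (list, tuple)):
        return [_plain(x) for x in v]
    return v


def write_csv(path, df: pd.DataFrame, cfg_hash: str, seed: int) -> None:
    """Write a CSV with the mandatory provenance comment line."""
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"# gazecells {__version__} config_hash={cfg_hash} seed={seed}\n")
        df.to_csv(fh, index=False)


def read_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", encoding="utf-8")


def _require_columns(df: pd.DataFrame, columns, path) -> None:
    for c in columns:
        if c not in df.columns:
            raise SchemaError(f"{path}: missing column {c!r}")


def _require_finite(df: pd.DataFrame, columns, path) -> None:
    for c in columns:
        vals = pd.to_numeric(df[c], errors="coerce").to_numpy()
        bad = np.flatnonzero(~np.isfinite(vals))
        if len(bad):
            raise SchemaError(
                f"{path}: row {int(bad[0])}, column {c!r}: non-numeric or "
                "non-finite value"
            )


def save_session(
    out_dir,
    trace: BehaviorTrace,
    events: TaskEvents,
    spikes: pd.DataFrame,
    waveforms: np.ndarray,
    cells: pd.DataFrame,
    arena: ArenaConfig,
    behavior: BehaviorConfig,
    task: TaskConfig,
    calibration: EyeCalibration,
    seed: int,
    bird_id: str = "synthetic",
    hemisphere: str = "left",
) -> SessionBundle:
    """Write one session as a bundle directory and return its manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    h = config_hash(arena, behavior, task, calibration, extra={"seed": seed})

    tr = pd.DataFrame(
        {
            "t": trace.t,
            "x": trace.position[:, 0],
            "y": trace.position[:, 1],
            "z": trace.position[:, 2],
            "qw": trace.quat_wxyz[:, 0],
            "qx": trace.quat_wxyz[:, 1],
            "qy": trace.quat_wxyz[:, 2],
            "qz": trace.quat_wxyz[:, 3],
            "light": events.light_state,
        }
    )
    write_csv(out / "trace.csv", tr, h, seed)
    write_csv(out / "trials.csv", events.trials, h, seed)
    write_csv(out / "spikes.csv", spikes, h, seed)
    wf = pd.DataFrame(
        waveforms, columns=[f"s{i}" for i in range(waveforms.shape[1])]
    )
    wf.insert(0, "cell_id", np.arange(len(wf)))
    write_csv(out / "waveforms.csv", wf, h, seed)
    write_csv(out / "cells.csv", cells, h, seed)
    save_configs(
        out / "configs.yaml",
        arena=arena, behavior=behavior, task=task, calibration=calibration,
    )
    bundle = SessionBundle(
        root=out,
        trace=out / "trace.csv",
        events=out / "trials.csv",
        spikes=out / "spikes.csv",
        waveforms=out / "waveforms.csv",
        cells=out / "cells.csv",
        configs=out / "configs.yaml",
        bird_id=bird_id,
        hemisphere=hemisphere,
        task_variant=task.variant,
        seed=seed,
    )
    bundle.to_yaml(out / "bundle.yaml")
    return bundle


def simulate_session(
    seed: int,
    out_dir,
    duration: float = 600.0,
    n_excitatory: int = 20,
    n_inh_peak: int = 4,
    n_inh_trough: int = 4,
    arena: Optional[ArenaConfig] = None,
    behavior: Optional[BehaviorConfig] = None,
    task: Optional[TaskConfig] = None,
    calibration: Optional[EyeCalibration] = None,
    hemisphere: str = "left",
) -> SessionBundle:
    """Generate behavior plus a spiking population and write the bundle."""
    arena = arena or ArenaConfig()
    behavior = behavior or BehaviorConfig()
    task = task or TaskConfig()
    calibration = calibration or EyeCalibration()
    trace, events, truth = generate_session(
        arena, behavior, task, duration=duration, rng_seed=seed
    )
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    specs = default_population(n_excitatory, n_inh_peak, n_inh_trough, arena, rng)
    spikes, waveforms, cells = generate_spike_population(
        specs, trace, truth.saccades, events.light_state, arena, calibration,
        rng, trials=events.trials, hemisphere=hemisphere,
    )
    return save_session(
        out_dir, trace, events, spikes, waveforms, cells,
        arena, behavior, task, calibration, seed, hemisphere=hemisphere,
    )


def load_session(bundle_path) -> Session:
    """Load and validate a bundle; raises :class:`SchemaError` on violations."""
    bundle_path = Path(bundle_path)
    if bundle_path.is_dir():
        bundle_path = bundle_path / "bundle.yaml"
    bundle = SessionBundle.from_yaml(bundle_path)
    for name in ("trace", "events", "spikes", "waveforms", "cells", "configs"):
        p = getattr(bundle, name)
        if not p.exists():
            raise SchemaError(f"{bundle_path}: referenced file missing: {p}")

    cfgs = load_configs(bundle.configs)
    arena = cfgs["arena"]
    behavior = cfgs["behavior"]
    task = cfgs["task"]
    calibration = cfgs["calibration"]

    tr = read_csv(bundle.trace)
    _require_columns(tr, TRACE_COLUMNS, bundle.trace)
    _require_finite(tr, TRACE_COLUMNS, bundle.trace)
    t = tr["t"].to_numpy(float)
    if len(t) < 2 or np.any(np.diff(t) <= 0):
        raise SchemaError(f"{bundle.trace}: column 't': not strictly increasing")
    quat = tr[["qw", "qx", "qy", "qz"]].to_numpy(float)
    norms = np.linalg.norm(quat, axis=1)
    bad = np.flatnonzero(np.abs(norms - 1.0) > 1e-3)
    if len(bad):
        raise SchemaError(
            f"{bundle.trace}: row {int(bad[0])}, column 'qw': quaternion "
            "is not unit norm"
        )
    trace = BehaviorTrace(
        t=t, position=tr[["x", "y", "z"]].to_numpy(float), quat_wxyz=quat
    )
    light = tr["light"].to_numpy(int)

    trials = read_csv(bundle.events)
    _require_columns(trials, ["trial", "target", "t_light_on"], bundle.events)
    on = trials["t_light_on"].to_numpy(float)
    on = on[np.isfinite(on)]
    if len(on) and (on.min() < t[0] or on.max() > t[-1]):
        i = int(np.argmax((trials["t_light_on"] < t[0]) | (trials["t_light_on"] > t[-1])))
        raise SchemaError(
            f"{bundle.events}: row {i}, column 't_light_on': outside the "
            "trace time range"
        )

    spikes = read_csv(bundle.spikes)
    _require_columns(spikes, SPIKE_COLUMNS, bundle.spikes)
    _require_finite(spikes, SPIKE_COLUMNS, bundle.spikes)
    st = spikes["t"].to_numpy(float)
    bad = np.flatnonzero((st < t[0]) | (st > t[-1]))
    if len(bad):
        raise SchemaError(
            f"{bundle.spikes}: row {int(bad[0])}, column 't': spike time "
            "beyond the trace time range"
        )

    wf = read_csv(bundle.waveforms)
    _require_columns(wf, ["cell_id"], bundle.waveforms)
    scols = [c for c in wf.columns if c.startswith("s")]
    if len(scols) != WAVEFORM_SAMPLES:
        raise SchemaError(
            f"{bundle.waveforms}: expected {WAVEFORM_SAMPLES} sample columns, "
            f"found {len(scols)}"
        )
    cells = read_csv(bundle.cells)
    _require_columns(cells, ["cell_id", "cell_type"], bundle.cells)
    cell_ids = set(cells["cell_id"].astype(int))
    wf_ids = set(wf["cell_id"].astype(int))
    if wf_ids != cell_ids:
        raise SchemaError(
            f"{bundle.waveforms}: column 'cell_id': ids do not match "
            f"{bundle.cells}"
        )
    sp_ids = set(spikes["cell_id"].astype(int))
    if not sp_ids <= cell_ids:
        extra = sorted(sp_ids - cell_ids)[0]
        row = int(np.argmax(spikes["cell_id"].to_numpy(int) == extra))
        raise SchemaError(
            f"{bundle.spikes}: row {row}, column 'cell_id': id {extra} has "
            "no waveform/metadata"
        )
    wf = wf.sort_values("cell_id")
    waveforms = wf[scols].to_numpy(float)

    return Session(
        trace=trace, light_state=light, trials=trials, spikes=spikes,
        waveforms=waveforms, cells=cells.sort_values("cell_id").reset_index(drop=True),
        arena=arena, behavior=behavior, task=task, calibration=calibration,
        bundle=bundle,
    )


# ---------------------------------------------------------------------------
# pipeline driver


def _stage_segment(session: Session, seed: int):
    from . import segmentation as seg

    feats = seg.compute_kinematic_features(session.trace, session.arena)
    spec = seg.build_hmm_spec(session.arena, feats)
    spec = seg.fit_observation_means(feats, spec, train_samples=90000)
    path, _ = seg.viterbi_decode(feats, spec)
    table = seg.refine_segments(path, feats, session.trace, spec)
    table = seg.annotate_saccade_gaze(
        table, session.trace, session.arena, session.calibration
    )
    return table


def _saccade_arrays(segments: pd.DataFrame, arena: ArenaConfig):
    """Reassemble (n, 2, n_sites) alpha arrays from annotated segment rows."""
    sac = segments[segments["state"] == "saccade"].reset_index(drop=True)
    n_sites = arena.n_sites
    a_prev = np.full((len(sac), 2, n_sites), np.nan)
    a_next = np.full((len(sac), 2, n_sites), np.nan)
    for eye, tag in ((0, "left"), (1, "right")):
        for s in range(n_sites):
            a_prev[:, eye, s] = sac[f"alpha_prev_{tag}_{s}"]
            a_next[:, eye, s] = sac[f"alpha_next_{tag}_{s}"]
    return sac, a_prev, a_next


def _stage_tuning(session: Session, segments: pd.DataFrame, seed: int):
    from . import tuning

    fixations = segments[segments["state"].isin(["fixation", "feed"])]
    n_sites = session.arena.n_sites
    duration = float(session.trace.t[-1] - session.trace.t[0])
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
    rows = []
    for cid, sub in session.spikes.groupby("cell_id"):
        st = np.sort(sub["t"].to_numpy(float))
        rates, occ = tuning.site_rates_and_occupancy(st, fixations, n_sites)
        info = tuning.site_information(rates, occ)

        def info_fn(times, fx=fixations, ns=n_sites):
            r, o = tuning.site_rates_and_occupancy(times, fx, ns)
            return tuning.site_information(r, o)

        shuf = tuning.shuffle_significance(st, info_fn, duration, rng=rng)
        rows.append(
            dict(
                cell_id=int(cid),
                mean_rate=len(st) / duration,
                site_information=info,
                p_value=shuf["p_value"],
                significant=bool(shuf["significant"]),
                preferred_site=tuning.preferred_site(rates),
                selectivity=tuning.selectivity_index(rates),
                **{f"site_rate_{s}": rates[s] for s in range(n_sites)},
            )
        )
    return pd.DataFrame(rows)


def _stage_glm(
    session: Session,
    segments: pd.DataFrame,
    seed: int,
    tau: float = None,
    lam: float = None,
):
    from . import glm

    tau = glm.DEFAULT_TAU if tau is None else tau
    lam = glm.DEFAULT_LAMBDA if lam is None else lam
    sac, _, a_next = _saccade_arrays(segments, session.arena)
    dashes = segments[segments["state"] == "dash"]
    contra = contralateral_eye(session.bundle.hemisphere)
    include = glm.saccade_inclusion_mask(sac, a_next, dashes, contra)
    outer = session.arena.outer_site_indices
    rows = []
    for cid, sub in session.spikes.groupby("cell_id"):
        st = np.sort(sub["t"].to_numpy(float))
        X, y, names, kept = glm.build_gaze_design(
            st, sac, a_next, session.arena, contra, tau=tau, include=include
        )
        if len(y) < 10:
            continue
        fit = glm.fit_poisson_lasso(X, y, lam=lam)
        nc = len(outer)
        j_pref = int(np.argmax(fit.coef[:nc]))
        nd = glm.normalized_difference(fit.coef[j_pref], fit.coef[nc + j_pref])
        pref = int(outer[j_pref])
        dev = glm.poisson_deviance(y, glm.predicted_means(X, fit))
        row = dict(cell_id=int(cid), beta0=fit.intercept, deviance=dev,
                   preferred_site=pref, norm_diff=nd, n_saccades=len(y))
        for j in range(nc):
            row[f"c{j + 1}"] = fit.coef[j]
        for j in range(nc):
            row[f"i{j + 1}"] = fit.coef[nc + j]
        rows.append(row)
    return pd.DataFrame(rows)


def _stage_temporal(session: Session, segments: pd.DataFrame, seed: int):
    from . import temporal

    sac = segments[segments["state"] == "saccade"]
    peaks = sac["t_peak"].to_numpy(float)
    peaks = peaks[np.isfinite(peaks)]
    rows = []
    for cid, sub in session.spikes.groupby("cell_id"):
        st = np.sort(sub["t"].to_numpy(float))
        centers, rate, n = temporal.event_aligned_rate(st, peaks)
        early, late = temporal.early_late_rates(centers, rate)
        rows.append(
            dict(cell_id=int(cid), early_rate=early, late_rate=late,
                 contrast=early - late, n_events=n)
        )
    return pd.DataFrame(rows)


def _stage_celltypes(session: Session, segments: pd.DataFrame, seed: int):
    from . import celltypes, temporal

    duration = float(session.trace.t[-1] - session.trace.t[0])
    counts = session.spikes.groupby("cell_id").size()
    feats = []
    for i, cid in enumerate(session.cells["cell_id"].astype(int)):
        n_spk = int(counts.get(cid, 0))
        f = celltypes.extract_waveform_features(
            session.waveforms[i], n_spk, duration
        )
        f["cell_id"] = cid
        f["n_spikes"] = n_spk
        feats.append(f)
    fdf = pd.DataFrame(feats)
    cls = celltypes.classify_ei_gmm(fdf, rng_seed=seed)
    out = pd.DataFrame(
        dict(
            cell_id=fdf["cell_id"],
            klass=cls.labels,
            n_spikes=fdf["n_spikes"],
            dist_e=cls.mahalanobis[:, 0],
            dist_i=cls.mahalanobis[:, 1],
        )
    ).rename(columns={"klass": "class"})
    out["excluded_reason"] = np.where(
        fdf["excluded"], f"fewer than {celltypes.MIN_SPIKES} spikes", ""
    )
    # interneuron peak/trough subtypes from saccade-aligned response phase
    sac = segments[segments["state"] == "saccade"]
    peaks = sac["t_peak"].to_numpy(float)
    peaks = peaks[np.isfinite(peaks)]
    phases = np.full(len(out), np.nan)
    inter = np.flatnonzero(out["class"].to_numpy() == "interneuron")
    for i in inter:
        cid = int(out["cell_id"].iloc[i])
        st = np.sort(
            session.spikes.loc[session.spikes["cell_id"] == cid, "t"].to_numpy(float)
        )
        centers, rate, _ = temporal.event_aligned_rate(st, peaks)
        try:
            phases[i] = celltypes.interneuron_phase(rate, centers)
        except ValueError:
            phases[i] = np.nan
    out["phase_rad"] = phases
    out["subtype"] = ""
    ok = inter[np.isfinite(phases[inter])]
    if len(ok) >= 2:
        rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
        res = celltypes.classify_interneuron_phases(phases[ok], rng=rng)
        out.loc[out.index[ok], "subtype"] = res["labels"]
    return out


def run_pipeline(
    bundle_path,
    out_dir,
    seed: int = 0,
    tau: Optional[float] = None,
    lam: Optional[float] = None,
) -> dict:
    """Run segment → tuning → glm → temporal → celltypes on a bundle.

    Writes one CSV per stage plus ``provenance.json`` into ``out_dir``. A
    stage failure is logged and recorded; earlier outputs are retained and
    independent later stages still run. Returns the provenance dict.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    session = load_session(bundle_path)
    h = config_hash(
        session.arena, session.behavior, session.task, session.calibration,
        extra={"seed": seed, "tau": tau, "lambda": lam},
    )
    import scipy
    import sklearn
    import statsmodels

    prov = {
        "config_hash": h,
        "seed": seed,
        "bundle": str(session.bundle.root),
        "versions": {
            "gazecells": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scipy": scipy.__version__,
            "scikit-learn": sklearn.__version__,
            "statsmodels": statsmodels.__version__,
        },
        "stages": {},
    }

    segments = None
    stages = [
        ("segment", lambda: _stage_segment(session, seed)),
        ("tuning", lambda: _stage_tuning(session, segments, seed)),
        ("glm", lambda: _stage_glm(session, segments, seed, tau=tau, lam=lam)),
        ("temporal", lambda: _stage_temporal(session, segments, seed)),
        ("celltypes", lambda: _stage_celltypes(session, segments, seed)),
    ]
    for name, fn in stages:
        if name != "segment" and segments is None:
            prov["stages"][name] = {"status": "skipped", "error": "no segments"}
            log.error("stage %s skipped: segmentation unavailable", name)
            continue
        t0 = time.time()
        try:
            result = fn()
            write_csv(out / f"{name}s.csv" if name == "segment" else out / f"{name}.csv",
                      result, h, seed)
            if name == "segment":
                segments = result
            prov["stages"][name] = {
                "status": "ok", "rows": int(len(result)),
                "seconds": round(time.time() - t0, 2),
            }
            log.info("stage %s: %d rows in %.1fs", name, len(result),
                     time.time() - t0)
        except Exception as exc:  # noqa: BLE001 - stage isolation is the contract
            prov["stages"][name] = {"status": "failed", "error": repr(exc)}
            log.exception("stage %s failed", name)
    with open(out / "provenance.json", "w") as fh:
        json.dump(prov, fh, indent=2, sort_keys=True)
    return prov
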