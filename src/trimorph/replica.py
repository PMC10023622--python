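"""End-to-end synthetic replica: cohort synthesis -> measurement -> report.

For every sample and condition the driver draws generator truths from the
packaged cohort targets, builds valve / flow / RV phantoms calibrated to
those truths, runs the full measurement pipelines on them, and emits a
summary table plus per-sample recovery diagnostics (measured vs generator
truth).

Derived quantities: the annulus phantom is a saddle-rimmed ellipse, so its
perimeters and areas follow from the sampled diameters; cardiac output
follows from the imposed stroke volume and the sampled regurgitant
fraction.  Their "configured target" is therefore the analytic truth of the
generated phantom, not an independent dial.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import hemodynamics as hd
from . import morphometry as mm
from . import rv_seg as rv
from . import synth_hemo as sh
from . import synth_valve as sv
from .cohort import PairedMeasurements, build_summary, summary_to_markdown
from .errors import TrimorphError
from .presets import default_cohort_config

__all__ = ["RunConfig", "ReplicaReport", "ReplicaStageError", "run_replica", "METRIC_ORDER"]

METRIC_ORDER = [
    "BF15",
    "BF30",
    "TRF",
    "CO",
    "PRV",
    "Dmax",
    "Dmin",
    "L2D",
    "L3D",
    "A2D",
    "A3D",
    "Tvol",
    "RV_volume",
]

_RV_BASE_AXES = (50.0, 40.0, 22.2)


class ReplicaStageError(TrimorphError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"replica stage {stage!r} failed: {cause}")


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    n_samples: int = 10
    paired_correlation: float = 0.8
    saddle_height: float = 3.5  # mm, annulus out-of-plane amplitude
    valve_spacing: float = 0.5  # mm
    valve_noise_sd: float = 0.0
    rv_spacing: float = 1.0  # mm
    rv_noise_sd: float = 5.0
    stroke_volume: float = 70.0  # mL
    heart_rate: float = 60.0  # bpm
    fs: float = 200.0  # Hz
    n_cycles: int = 10
    rp: float = 1.0  # mmHg s / mL
    snr_db: float = float("inf")
    n_quad: int = 20_000
    save_volumes: bool = False

    def as_dict(self) -> dict:
        d = asdict(self)
        d["snr_db"] = "inf" if np.isposinf(self.snr_db) else self.snr_db
        return d

    @property
    def config_hash(self) -> str:
        payload = json.dumps(self.as_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


@dataclass
class ReplicaReport:
    config: RunConfig
    summary: pd.DataFrame  # measured cohort summary
    truth_summary: pd.DataFrame  # generator-truth cohort summary
    recovery: pd.DataFrame  # per sample/condition/metric truth vs measured
    out_dir: Path | None = None
    files: list[str] = field(default_factory=list)


def _stage_seed(seed: int, *tags: int) -> int:
    return int(np.random.SeedSequence((seed, *tags)).generate_state(1)[0])


def _clamp_truths(truths: dict[str, sv.PairedTruth]) -> dict[str, np.ndarray]:
    """Per-sample validity clamps so every draw yields a buildable phantom."""
    vals = {
        name: {"fresh": t.fresh.copy(), "defrosted": t.defrosted.copy()}
        for name, t in truths.items()
    }
    for cond in ("fresh", "defrosted"):
        dmax = vals["Dmax"][cond]
        dmin = vals["Dmin"][cond]
        np.clip(dmax, 25.0, None, out=dmax)
        np.minimum(dmin, dmax - 2.0, out=dmin)
        np.clip(dmin, 20.0, None, out=dmin)
        np.clip(vals["Tvol"][cond], 0.5, None, out=vals["Tvol"][cond])
        np.clip(vals["TRF"][cond], 0.0, 99.0, out=vals["TRF"][cond])
        np.clip(vals["PRV"][cond], 0.0, None, out=vals["PRV"][cond])
        np.clip(vals["BF15"][cond], 0.05, None, out=vals["BF15"][cond])
        np.clip(vals["BF30"][cond], 0.05, None, out=vals["BF30"][cond])
        np.clip(vals["RV_volume"][cond], 50.0, None, out=vals["RV_volume"][cond])
    return vals


def _morpho_sample(
    cfg: RunConfig, dmax: float, dmin: float, tvol: float, seed: int
) -> tuple[dict[str, float], dict[str, float]]:
    a, b = dmax / 2.0, dmin / 2.0
    cos_c = np.zeros((3, 5))
    sin_c = np.zeros((3, 5))
    cos_c[0, 1] = a
    sin_c[1, 1] = b
    cos_c[2, 2] = cfg.saddle_height
    annulus = sv.AnnulusModel(order=4, cos_coeffs=cos_c, sin_coeffs=sin_c)
    h = 2000.0 * tvol / (np.pi * a * b)  # elliptic-paraboloid closed form
    spec = sv.LeafletPhantomSpec(
        annulus=annulus, tenting_profile="paraboloid", tenting_depth=h
    )
    truth = sv.analytic_truth(annulus, spec, n_quad=cfg.n_quad)
    _, annotation = sv.voxelize_valve(
        spec, spacing=cfg.valve_spacing, noise_sd=cfg.valve_noise_sd, seed=seed
    )
    measured = mm.run_morphometry(annotation).as_dict()
    return truth, measured


def _hemo_sample(
    cfg: RunConfig, trf: float, prv: float, seed: int
) -> tuple[dict[str, float], dict[str, float]]:
    settings = sh.PumpSettings(
        heart_rate=cfg.heart_rate, stroke_volume=cfg.stroke_volume, fs=cfg.fs
    )
    wk = sh.WindkesselParams(Rp=cfg.rp)
    wf = sh.make_flow_set(
        settings,
        wk,
        trf_target=trf,
        prv_target=prv,
        n_cycles=cfg.n_cycles,
        snr_db=cfg.snr_db,
        seed=seed,
    )
    cycle = hd.ensemble_average(wf, n_cycles=cfg.n_cycles)
    idx = hd.compute_indexes(cycle, stroke_volume=cfg.stroke_volume)
    co_truth = 0.06 * cfg.stroke_volume * (1.0 - trf / 100.0) / settings.period
    truth = {"TRF": trf, "CO": co_truth, "PRV": prv}
    return truth, idx.as_dict()


def _backflow_sample(cfg: RunConfig, target: float, delta_p: float) -> float:
    orifice = sh.calibrate_eroa(target, delta_p)
    value = sh.steady_backflow(orifice, delta_p)
    t = np.arange(int(10.0 * cfg.fs)) / cfg.fs
    record = value * (1.0 - np.exp(-t / 0.3))
    return hd.measure_steady_backflow(record, fs=cfg.fs).value_lmin


def _rv_sample(cfg: RunConfig, target_ml: float, seed: int) -> tuple[float, float]:
    base = np.asarray(_RV_BASE_AXES)
    v0 = 4.0 / 3.0 * np.pi * np.prod(base) / 1000.0
    axes = tuple(base * (target_ml / v0) ** (1.0 / 3.0))
    spec = sv.RVPhantomSpec(semi_axes=axes, noise_sd=cfg.rv_noise_sd, seed=seed)
    vol, truth = sv.build_rv_phantom(spec, spacing=cfg.rv_spacing)
    thr = rv.ThresholdSpec(
        lower=spec.cavity_intensity - 3.0 * max(cfg.rv_noise_sd, 1.0),
        upper=spec.cavity_intensity + 3.0 * max(cfg.rv_noise_sd, 1.0),
    )
    seed_idx = tuple(int(round(v)) for v in vol.world_to_index(np.zeros(3)))
    _, measured = rv.segment_rv(vol, thr, seeds=[seed_idx])
    return truth, measured


def run_replica(config: RunConfig, out_dir: str | Path | None = None) -> ReplicaReport:
    """Run the full synthetic cohort experiment; see module docstring."""
    cohort_cfg = default_cohort_config(
        seed=config.seed,
        n_samples=config.n_samples,
        paired_correlation=config.paired_correlation,
    )
    try:
        truths = _clamp_truths(sv.sample_cohort(cohort_cfg))
    except Exception as exc:  # pragma: no cover
        raise ReplicaStageError("cohort-sampling", exc) from exc

    rows = []
    for i in range(config.n_samples):
        for j, cond in enumerate(("fresh", "defrosted")):
            def record(metric, truth, measured):
                rows.append(
                    {
                        "metric": metric,
                        "sample_id": i,
                        "condition": cond,
                        "truth": float(truth),
                        "measured": float(measured),
                    }
                )

            try:
                t_m, m_m = _morpho_sample(
                    config,
                    truths["Dmax"][cond][i],
                    truths["Dmin"][cond][i],
                    truths["Tvol"][cond][i],
                    seed=_stage_seed(config.seed, i, j, 1),
                )
                for metric in ("L2D", "L3D", "A2D", "A3D", "Dmax", "Dmin", "Tvol"):
                    record(metric, t_m[metric], m_m[metric])
            except TrimorphError:
                raise
            except Exception as exc:
                raise ReplicaStageError("morphometry", exc) from exc

            try:
                t_h, m_h = _hemo_sample(
                    config,
                    truths["TRF"][cond][i],
                    truths["PRV"][cond][i],
                    seed=_stage_seed(config.seed, i, j, 2),
                )
                for metric in ("TRF", "CO", "PRV"):
                    record(metric, t_h[metric], m_h[metric])
            except Exception as exc:
                raise ReplicaStageError("hemodynamics", exc) from exc

            try:
                for metric, dp in (("BF15", 15.0), ("BF30", 30.0)):
                    target = truths[metric][cond][i]
                    record(metric, target, _backflow_sample(config, target, dp))
            except Exception as exc:
                raise ReplicaStageError("steady-backflow", exc) from exc

            try:
                t_rv, m_rv = _rv_sample(
                    config,
                    truths["RV_volume"][cond][i],
                    seed=_stage_seed(config.seed, i, j, 3),
                )
                record("RV_volume", t_rv, m_rv)
            except Exception as exc:
                raise ReplicaStageError("rv-segmentation", exc) from exc

    recovery = pd.DataFrame(rows)
    recovery["rel_err_pct"] = 100.0 * (recovery["measured"] - recovery["truth"]) / recovery[
        "truth"
    ]

    def paired(metric: str, column: str) -> PairedMeasurements:
        sel = recovery[recovery["metric"] == metric]
        wide = sel.pivot_table(
            index="sample_id", columns="condition", values=column, sort=False
        )
        return PairedMeasurements(
            metric=metric,
            sample_ids=list(wide.index),
            fresh=wide["fresh"].to_numpy(),
            defrosted=wide["defrosted"].to_numpy(),
        )

    summary = build_summary([paired(m, "measured") for m in METRIC_ORDER])
    truth_summary = build_summary([paired(m, "truth") for m in METRIC_ORDER])

    report = ReplicaReport(
        config=config, summary=summary, truth_summary=truth_summary, recovery=recovery
    )
    if out_dir is not None:
        report.out_dir = Path(out_dir)
        _write_bundle(report)
    return report


def _write_bundle(report: ReplicaReport) -> None:
    out = report.out_dir
    out.mkdir(parents=True, exist_ok=True)
    cfg = report.config
    stamp = f"# config_hash={cfg.config_hash} seed={cfg.seed}\n"

    def write_csv(df: pd.DataFrame, name: str) -> None:
        path = out / name
        with open(path, "w") as fh:
            fh.write(stamp)
            df.to_csv(fh, index=False, float_format="%.10g")
        report.files.append(name)

    write_csv(report.summary, "summary.csv")
    write_csv(report.truth_summary, "truth_summary.csv")
    write_csv(report.recovery, "recovery.csv")

    with open(out / "summary.md", "w") as fh:
        fh.write(stamp.replace("#", "<!--").rstrip() + " -->\n\n")
        fh.write(summary_to_markdown(report.summary))
    report.files.append("summary.md")

    payload = {
        "config": cfg.as_dict(),
        "config_hash": cfg.config_hash,
        "summary": report.summary.to_dict(orient="records"),
        "truth_summary": report.truth_summary.to_dict(orient="records"),
        "max_abs_rel_err_pct": {
            m: float(
                report.recovery.loc[report.recovery["metric"] == m, "rel_err_pct"]
                .abs()
                .max()
            )
            for m in METRIC_ORDER
        },
    }
    with open(out / "report.json", "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")
    report.files.append("report.json")
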