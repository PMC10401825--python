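"""End-to-end orchestration: phantom (or files) -> registration -> strain,
aeration, recruitment, ROI profiles -> machine-readable report.

`run_case` executes the full single-subject analysis and writes all NIfTI
intermediates, CSV tables, and a JSON report containing every scalar
metric together with the configuration, seed, and (for phantom runs) a
ground-truth recovery block. `compare_strategies` pairs the per-subject
reports of two ventilatory strategies and runs the paired statistics.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import aeration as aer
from . import recruitment as rec
from . import registration as reg
from . import stats
from . import strain_analytics as sa
from .core_io import AerationMap, read_mask, read_volume, write_volume
from .phantom import PhantomSpec, generate

__all__ = ["RunConfig", "run_case", "compare_strategies"]

log = logging.getLogger("lungstrain.pipeline")


@dataclass
class RunConfig:
    """Configuration of one end-to-end case."""

    # exactly one input source: a phantom spec, or the four file paths
    phantom_spec: PhantomSpec | None = None
    ee_path: str | None = None
    ei_path: str | None = None
    ee_mask_path: str | None = None
    ei_mask_path: str | None = None
    registration: reg.RegistrationConfig = field(default_factory=reg.RegistrationConfig)
    n_rois: int = 10
    run_registration: bool = True
    run_prm: bool = True
    out_dir: str | None = None
    seed: int | None = None  # overrides the phantom spec seed
    subject: str = "case"

    def __post_init__(self) -> None:
        file_input = all(
            p is not None
            for p in (self.ee_path, self.ei_path, self.ee_mask_path, self.ei_mask_path)
        )
        if (self.phantom_spec is None) == (not file_input):
            raise ValueError(
                "exactly one input source required: a phantom spec, or all "
                "four volume/mask paths"
            )


def _config_hash(cfg: RunConfig) -> str:
    def enc(o):
        if dataclasses.is_dataclass(o):
            return {k: enc(v) for k, v in dataclasses.asdict(o).items()}
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, (tuple, list)):
            return [enc(v) for v in o]
        return o

    blob = json.dumps(enc(cfg), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _load_inputs(cfg: RunConfig):
    if cfg.phantom_spec is not None:
        spec = cfg.phantom_spec
        if cfg.seed is not None:
            spec = dataclasses.replace(spec, seed=cfg.seed)
        case = generate(spec)
        return case.ee, case.ei, case.ee_mask, case.ei_mask, case.truth
    ee = read_volume(cfg.ee_path)
    ei = read_volume(cfg.ei_path)
    return ee, ei, read_mask(cfg.ee_mask_path), read_mask(cfg.ei_mask_path), None


def _aeration_block(fgas: AerationMap, label: str) -> dict:
    masses = aer.mass_summary(fgas)
    het = aer.heterogeneity(fgas)
    return {
        f"{label}_mean_fgas": float(fgas.in_mask().mean()),
        f"{label}_p95_fgas": aer.percentile95(fgas),
        f"{label}_cov_fgas": het.cov,
        f"{label}_gas_volume_ml": masses.gas_volume_ml,
        f"{label}_total_mass_g": masses.total_mass_g,
        **{f"{label}_percent_{c}": masses.percent[c] for c in masses.percent},
    }


def run_case(cfg: RunConfig) -> dict:
    """Run the full analysis for one case and return the report dict.

    When ``cfg.out_dir`` is set, intermediates (NIfTI), tables (CSV), and
    the report (JSON) are written there; partial outputs are retained if a
    stage fails.
    """
    t_start = time.time()
    out = Path(cfg.out_dir) if cfg.out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "subject": cfg.subject,
        "config_hash": _config_hash(cfg),
        "seed": cfg.seed
        if cfg.seed is not None
        else (cfg.phantom_spec.seed if cfg.phantom_spec else None),
        "stages": {},
    }

    def _stage(name):
        log.info("stage %s", name)
        report["stages"][name] = {"t_start_s": round(time.time() - t_start, 2)}

    try:
        _stage("inputs")
        ee, ei, ee_mask, ei_mask, truth = _load_inputs(cfg)
        if out:
            write_volume(ee, out / "ee.nii.gz")
            write_volume(ei, out / "ei.nii.gz")
            write_volume(ee_mask, out / "ee_mask.nii.gz")
            write_volume(ei_mask, out / "ei_mask.nii.gz")

        _stage("aeration")
        fgas_ee = aer.hu_to_fgas(ee, ee_mask)
        fgas_ei = aer.hu_to_fgas(ei, ei_mask)
        masses_ee = aer.mass_summary(fgas_ee)
        masses_ei = aer.mass_summary(fgas_ei)
        report.update(_aeration_block(fgas_ee, "ee"))
        report.update(_aeration_block(fgas_ei, "ei"))
        report["eelv_ml"] = masses_ee.gas_volume_ml
        report["delta_aeration"] = sa.delta_aeration(
            report["ei_mean_fgas"], report["ee_mean_fgas"]
        )
        if out:
            write_volume(fgas_ee, out / "fgas_ee.nii.gz")
            write_volume(fgas_ei, out / "fgas_ei.nii.gz")

        _stage("recruitment")
        report["tidal_recruitment"] = rec.tidal_recruitment(masses_ee, masses_ei)
        part_ee = rec.vertical_rois(ee_mask, cfg.n_rois)
        part_ei = rec.vertical_rois(ei_mask, cfg.n_rois)
        regional_tr = rec.regional_recruitment(fgas_ee, fgas_ei, part_ee, part_ei)
        report["regional_recruitment"] = [float(v) for v in regional_tr]
        intratidal = rec.intratidal_change(masses_ee, masses_ei)
        report["intratidal_change"] = {
            c: {
                "delta_g": float(intratidal.loc[c, "delta_g"]),
                "delta_percent_of_ee_mass": float(
                    intratidal.loc[c, "delta_percent_of_ee_mass"]
                ),
            }
            for c in intratidal.index
        }
        if out:
            intratidal.to_csv(out / "intratidal_change.csv")

        strain = None
        if cfg.run_registration:
            _stage("registration")
            pair = reg.preprocess_pair(
                ee, ei, ei_mask, ee_mask=ee_mask, cfg=cfg.registration
            )
            res = reg.register(pair, cfg.registration)
            report["registration"] = {
                "final_metric": res.final_metric,
                "min_jacobian": res.min_jacobian,
                "max_jacobian": res.max_jacobian,
                "stages": [
                    {k: v for k, v in s.items() if k != "metric_history"}
                    for s in res.stage_log
                ],
            }
            _stage("strain")
            jac, strain = reg.jacobian_map(res.field, ee_mask)
            ssum = sa.strain_summary(strain)
            report["strain_mean"] = ssum.mean
            report["strain_p95"] = ssum.p95
            report["strain_cov"] = ssum.cov
            report["strain_heterogeneity_cov"] = aer.heterogeneity(strain).cov
            if out:
                write_volume(res.field, out / "displacement.nii.gz")
                write_volume(strain, out / "strain.nii.gz")

            _stage("strain_aeration")
            pulled, n_outside = sa.ei_aeration_on_ee_grid(
                fgas_ei, res.field, strain.mask
            )
            if n_outside:
                log.warning("%d voxels mapped outside the EI grid", n_outside)
            joint = sa.strain_vs_aeration(strain, pulled)
            report["strain_by_aeration_interval"] = [
                {
                    "interval": list(i.interval),
                    "median": i.median,
                    "iqr": list(i.iqr) if i.iqr else None,
                    "count": i.count,
                }
                for i in joint.intervals
            ]
            if cfg.run_prm:
                prm_map = sa.prm(fgas_ee, pulled, strain)
                report["prm_reported_bins"] = int(prm_map.reported.sum())
                if out:
                    np.savetxt(
                        out / "prm_volume_fraction.csv",
                        prm_map.volume_fraction,
                        delimiter=",",
                    )
                    np.savetxt(
                        out / "prm_mean_strain.csv", prm_map.mean_strain, delimiter=","
                    )

        _stage("roi_profiles")
        prof_ee = rec.roi_profile(part_ee, fgas_ee, strain)
        prof_ei = rec.roi_profile(part_ei, fgas_ei)
        report["roi_profile_ee"] = json.loads(prof_ee.to_json(orient="index"))
        report["roi_profile_ei"] = json.loads(prof_ei.to_json(orient="index"))
        if out:
            prof_ee.to_csv(out / "roi_profile_ee.csv")
            prof_ei.to_csv(out / "roi_profile_ei.csv")

        if truth is not None:
            _stage("truth_recovery")
            recovery = {
                "true_recruited_mass_fraction": truth.recruited_mass_fraction,
                "tr_error": report["tidal_recruitment"]
                - truth.recruited_mass_fraction,
                "mass_conservation_error": abs(
                    masses_ei.total_mass_g - masses_ee.total_mass_g
                )
                / masses_ee.total_mass_g,
            }
            if strain is not None:
                serr = np.abs(
                    (strain.data - (truth.jacobian - 1.0))[strain.mask]
                )
                recovery["strain_mae"] = float(serr.mean())
                recovery["strain_median_abs_error"] = float(np.median(serr))
                epe = np.linalg.norm(
                    res.field.data - truth.field.data, axis=-1
                )[ee_mask.data]
                recovery["median_endpoint_error_mm"] = float(np.median(epe))
                recovery["true_mean_strain"] = float(
                    (truth.jacobian - 1.0)[strain.mask].mean()
                )
            report["truth_recovery"] = recovery
    except Exception as exc:  # noqa: BLE001 - stage-tagged rethrow
        stage = list(report["stages"])[-1] if report["stages"] else "setup"
        if out:
            (out / "report_partial.json").write_text(json.dumps(report, indent=2))
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc

    report["runtime_s"] = round(time.time() - t_start, 2)
    if out:
        (out / "report.json").write_text(json.dumps(report, indent=2))
    return report


#: scalar report fields compared between strategies
_SCALAR_METRICS = (
    "ee_mean_fgas",
    "ei_mean_fgas",
    "ee_p95_fgas",
    "ei_p95_fgas",
    "ee_cov_fgas",
    "ei_cov_fgas",
    "eelv_ml",
    "delta_aeration",
    "tidal_recruitment",
    "strain_mean",
    "strain_p95",
    "strain_cov",
)


def compare_strategies(
    reports_a: list[dict], reports_b: list[dict]
) -> dict:
    """Paired comparison of two strategies across matched subjects.

    ``reports_a`` and ``reports_b`` are per-subject `run_case` reports,
    matched by their ``subject`` field. Returns paired differences and
    t-tests per scalar metric, the delta-aeration vs mean-strain
    correlation across all cases, and a region x strategy repeated-
    measures ANOVA on the ROI mean-aeration profiles.
    """
    subjects_a = {r["subject"]: r for r in reports_a}
    subjects_b = {r["subject"]: r for r in reports_b}
    if set(subjects_a) != set(subjects_b):
        raise ValueError("unmatched subject sets between strategies")
    subjects = sorted(subjects_a)
    if len(subjects) < 2:
        raise ValueError("need at least two matched subjects")
    out: dict = {"subjects": subjects, "metrics": {}}
    for metric in _SCALAR_METRICS:
        if any(metric not in subjects_a[s] or metric not in subjects_b[s] for s in subjects):
            continue
        a = np.array([subjects_a[s][metric] for s in subjects], dtype=float)
        b = np.array([subjects_b[s][metric] for s in subjects], dtype=float)
        entry = {
            "mean_a": float(a.mean()),
            "mean_b": float(b.mean()),
            "mean_difference": float((a - b).mean()),
        }
        try:
            t = stats.paired_t(stats.PairedSample(subjects=subjects, a=a, b=b))
            entry.update(t=t.t, df=t.df, p=t.p)
        except ValueError:
            entry.update(t=None, df=None, p=None)
        out["metrics"][metric] = entry
    # delta aeration vs mean strain across all cases (both strategies)
    has_strain = all(
        "strain_mean" in subjects_a[s] and "strain_mean" in subjects_b[s]
        for s in subjects
    )
    if has_strain:
        d_aer = [subjects_a[s]["delta_aeration"] for s in subjects] + [
            subjects_b[s]["delta_aeration"] for s in subjects
        ]
        m_str = [subjects_a[s]["strain_mean"] for s in subjects] + [
            subjects_b[s]["strain_mean"] for s in subjects
        ]
        corr = stats.correlation(d_aer, m_str, method="pearson")
        out["delta_aeration_vs_mean_strain"] = {
            "r": corr.r,
            "r2": corr.r**2,
            "p": corr.p,
            "n": corr.n,
        }
    # ROI x strategy repeated-measures ANOVA on EE mean aeration profiles
    try:
        # value per (subject, roi, strategy)
        arr = np.array(
            [
                [
                    [
                        subjects_a[s]["roi_profile_ee"][str(k)]["mean_fgas"],
                        subjects_b[s]["roi_profile_ee"][str(k)]["mean_fgas"],
                    ]
                    for k in range(1, 11)
                ]
                for s in subjects
            ]
        )
        anova = stats.rm_anova_two_way(arr)
        out["roi_anova_ee_mean_fgas"] = json.loads(anova.to_json(orient="index"))
    except (KeyError, ValueError):
        out["roi_anova_ee_mean_fgas"] = None
    return out
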