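"""End-to-end pipeline: one config in, one JSON-ready report out.

A run config is a mapping with any of the stage keys ``kinetics``,
``leaflet``, ``defects`` and ``labeling``; each stage generates its inputs
synthetically (or could be pointed at real files through the CLI) and runs
the corresponding analysis.  The report is deterministic for a given seed,
apart from its timestamp field.
"""

from __future__ import annotations

import datetime

import numpy as np

from . import defects as dfx
from . import io as fio
from . import kinetics as kin
from . import leaflets as lfl
from . import synthetic as syn
from .errors import DomainError

__all__ = ["run_end_to_end", "STAGES"]

STAGES = ("kinetics", "leaflet", "defects", "labeling")


def _kinetics_stage(cfg: dict, seed: int) -> dict:
    params = syn.KineticParams(
        E_A=float(cfg["E_A"]),
        nu0=float(cfg["nu0"]),
        temperatures=tuple(cfg.get("temperatures", syn.DEFAULT_TEMPERATURES)),
        noise_cv=float(cfg.get("noise_cv", 0.1)),
        n_replicates=int(cfg.get("n_replicates", 5)),
        seed=seed,
    )
    traces = syn.simulate_temperature_series(params)
    speeds = kin.speeds_from_traces(
        traces, window_frac=float(cfg.get("window_frac", 0.1))
    )
    method = cfg.get("method", "loglinear")
    pooled = kin.fit_arrhenius(speeds, method=method)
    per_exp = kin.fit_per_experiment(speeds, method=method)
    average_fit = kin.fit_arrhenius(speeds.averaged(), method=method)
    summary = kin.aggregate_fits(per_exp, average_fit=average_fit)
    return {
        "generating": {"E_A": params.E_A, "nu0": params.nu0},
        "pooled_fit": {
            "E_A": pooled.E_A,
            "E_A_sem": pooled.E_A_sem,
            "nu0": pooled.nu0,
            "n": pooled.n,
        },
        "summary": {
            "E_A_mean": summary.E_A,
            "E_A_sem": summary.E_A_sem,
            "nu0_average_fit": summary.nu0,
            "n_experiments": summary.n_fits,
        },
        "speeds": speeds.data.to_dict(orient="records"),
    }


def _leaflet_stage(cfg: dict) -> dict:
    lipid = lfl.LipidSpec(c0=float(cfg["c0"]), a=float(cfg["area"]), name=cfg.get("name", ""))
    table = lfl.partition_table(
        lipid,
        kappa=float(cfg["kappa"]),
        R=float(cfg["radius"]),
        fractions=[float(f) for f in cfg["fractions"]],
    )
    return {
        "parameters": {
            "kappa_kBT": float(cfg["kappa"]),
            "area_nm2": float(cfg["area"]),
            "c0_per_nm": float(cfg["c0"]),
            "radius_nm": float(cfg["radius"]),
        },
        "table": table.to_dict(orient="records"),
    }


def _defects_stage(cfg: dict) -> dict:
    spec = syn.ToyBilayerSpec(
        box_x=float(cfg["box_x"]),
        box_y=float(cfg["box_y"]),
        hole_rects=tuple(tuple(r) for r in cfg.get("hole_rects", ())),
    )
    snapshot = syn.build_toy_bilayer(spec)
    classifier = dfx.toy_classifier(spec.bead_radius)
    dmap = dfx.rasterize_leaflet(
        snapshot, "upper", classifier, cell_size=float(cfg.get("cell_size", 1.0))
    )
    out = {"ground_truth_fraction": spec.ground_truth_defect_fraction()}
    for category in ("deep", "shallow", "all"):
        stats = dfx.defect_surface_fraction([dmap], category=category)
        out[category] = {
            "fraction": stats.fraction,
            "n_components": len(stats.components),
        }
    return out


def _labeling_stage(cfg: dict, seed: int) -> dict:
    truth = syn.LabelingTruth(
        f=float(cfg["f"]),
        frac_external=float(cfg["frac_external"]),
        noise_cv=float(cfg.get("noise_cv", 0.0)),
        seed=seed,
    )
    intensities = syn.simulate_labeling_experiment(truth)
    fe = lfl.external_fraction_from_labeling(*intensities)
    occ = lfl.occupancy_from_external_fraction(truth.f, fe)
    return {
        "true_frac_external": truth.frac_external,
        "recovered_frac_external": fe,
        "f_i": occ.f_i,
        "f_o": occ.f_o,
        "r_hat": occ.r_hat,
    }


def run_end_to_end(config: dict, seed: int = 0) -> dict:
    """Run every stage present in ``config`` and assemble one report.

    Raises
    ------
    DomainError
        If the config enables no known stage ("nothing to do").
    """
    enabled = [s for s in STAGES if config.get(s)]
    if not enabled:
        raise DomainError(
            f"nothing to do: config enables none of the stages {STAGES}"
        )
    children = np.random.SeedSequence(seed).spawn(len(STAGES))
    stage_seed = {
        s: int(c.generate_state(1)[0] % (2**31)) for s, c in zip(STAGES, children)
    }
    report: dict = {
        "config_hash": fio.config_hash(config),
        "seed": seed,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "stages": enabled,
    }
    if "kinetics" in enabled:
        report["kinetics"] = _kinetics_stage(config["kinetics"], stage_seed["kinetics"])
    if "leaflet" in enabled:
        report["leaflet"] = _leaflet_stage(config["leaflet"])
    if "defects" in enabled:
        report["defects"] = _defects_stage(config["defects"])
    if "labeling" in enabled:
        report["labeling"] = _labeling_stage(config["labeling"], stage_seed["labeling"])
    return report
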