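"""End-to-end orchestration: generate/load → fit → descriptors → compare.

A run is driven by one config mapping (YAML on disk) and writes, under its
output directory: per-neuron fit reports (JSON), descriptor tables (CSV),
per-neuron summary scalars (CSV), comparison-graph statistics (CSV), the
percent-significant matrix (CSV), and a manifest with the config, seed and
package version.  All stages are deterministic given the config, so a rerun
reproduces every numeric output bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

import taucable
from taucable import comparison
from taucable.cable_model import MembraneParams, compartmentalize
from taucable.descriptors import (
    area_weighted_mean,
    descriptor_table,
    electrotonic_summary,
)
from taucable.fitting import FitTargets, fit_membrane
from taucable.morphology import distribution_by_distance, read_swc, write_swc
from taucable.synthetic_data import load_presets, sample_population

log = logging.getLogger(__name__)

COMPARED_DESCRIPTORS = (
    "v_transfer_ss",
    "v_transfer_50hz",
    "c_transfer",
    "delay_total",
    "rise_10_90",
    "half_width",
)

DEFAULT_CONFIG: dict = {
    "seed": 1,
    "groups": {
        "WT": {
            "source": "preset",
            "preset": "wt_like",
            "n_neurons": 10,
            "targets": {"Rin": 197.0, "tau": 32.5},
            "rest": -75.0,
        },
        "TG": {
            "source": "preset",
            "preset": "tg_like",
            "n_neurons": 10,
            "targets": {"Rin": 228.0, "tau": 35.2},
            "rest": -65.0,
        },
    },
    "membrane": {"Ra": 150.0, "spine_area": 1.5},
    "solver": {"dt": 0.025, "epsp_window": 400.0},
    "descriptors": {"include_epsp_shape": True},
    "statistics": {"alpha": 0.05, "posthoc_test": "t"},
}


def load_config(path: str | Path | None) -> dict:
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    if path is not None:
        user = yaml.safe_load(Path(path).read_text()) or {}
        _deep_update(cfg, user)
    return cfg


def _deep_update(base: dict, extra: Mapping) -> None:
    for k, v in extra.items():
        if isinstance(v, Mapping) and isinstance(base.get(k), dict):
            _deep_update(base[k], v)
        else:
            base[k] = v


def _load_group_morphologies(name: str, gcfg: dict, seed: int):
    if gcfg["source"] == "preset":
        presets = load_presets()
        gp = presets[gcfg["preset"]]
        morphs = sample_population(gp, gcfg["n_neurons"], seed)
        spine_density = gp.spine_density
    elif gcfg["source"] == "swc_dir":
        swc_dir = Path(gcfg["path"])
        if not swc_dir.is_dir():
            raise FileNotFoundError(f"group {name}: SWC directory {swc_dir} not found")
        morphs = [read_swc(p) for p in sorted(swc_dir.glob("*.swc"))]
        spine_density = gcfg["spine_density"]
    else:
        raise ValueError(f"group {name}: unknown source {gcfg['source']!r}")
    if not morphs:
        raise ValueError(f"group {name}: no morphologies")
    return morphs, spine_density


def run_pipeline(cfg: dict, out_dir: str | Path) -> Path:
    """Execute the full analysis; returns the run directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    dt = cfg["solver"]["dt"]
    epsp_window = cfg["solver"]["epsp_window"]
    include_epsp = cfg["descriptors"]["include_epsp_shape"]

    tables: dict[str, pd.DataFrame] = {}
    group_of: dict[str, str] = {}
    fit_rows, summary_rows, dist_rows = [], [], []

    for gname, gcfg in cfg["groups"].items():
        seed = int(cfg["seed"]) + {"WT": 0, "TG": 1}.get(gname, 7)
        morphs, spine_density = _load_group_morphologies(gname, gcfg, seed)
        targets = FitTargets(gcfg["targets"]["Rin"], gcfg["targets"]["tau"])
        p0 = MembraneParams(
            Ra=cfg["membrane"]["Ra"],
            E_leak=gcfg["rest"],
            spine_density=spine_density,
            spine_area=cfg["membrane"]["spine_area"],
        )
        for m in morphs:
            stage = f"fit[{gname}/{m.name}]"
            try:
                fitted, rep = fit_membrane(m, targets, p0)
            except Exception as exc:  # pragma: no cover - stage tagging
                raise RuntimeError(f"{stage}: {exc}") from exc
            fit_rows.append({"neuron": m.name, "group": gname, **rep.to_dict()})
            model = compartmentalize(m, fitted)
            tbl = descriptor_table(
                model, neuron=m.name, include_epsp_shape=include_epsp,
                epsp_t_stop=epsp_window, dt=dt,
            )
            tables[m.name] = tbl
            group_of[m.name] = gname
            es = electrotonic_summary(model)
            row = {"neuron": m.name, "group": gname}
            for arbor in ("apical", "basal"):
                sub = tbl[tbl["arbor"] == arbor]
                for d in COMPARED_DESCRIPTORS:
                    if not sub.empty and not sub[d].isna().all():
                        row[f"awm_{d}_{arbor}"] = area_weighted_mean(tbl, d, arbor)
                er = es[es["arbor"] == arbor]
                if not er.empty:
                    row[f"mean_L_{arbor}"] = float(er["mean_L"].iloc[0])
                    row[f"var_L_{arbor}"] = float(er["var_L"].iloc[0])
            summary_rows.append(row)
            for arbor in ("apical", "basal"):
                for q in ("length", "area"):
                    try:
                        d = distribution_by_distance(m, q, 50.0, arbor)
                    except Exception:
                        continue
                    d.insert(0, "quantity", q)
                    d.insert(0, "arbor", arbor)
                    d.insert(0, "group", gname)
                    d.insert(0, "neuron", m.name)
                    dist_rows.append(d)
            log.info("%s done (Rm=%.0f, Cm=%.3f)", stage, rep.Rm, rep.Cm)

    fits = pd.DataFrame(fit_rows)
    fits.to_csv(out / "fit_reports.csv", index=False)
    (out / "fit_reports.json").write_text(fits.to_json(orient="records", indent=1))
    summary = pd.DataFrame(summary_rows)
    summary.to_csv(out / "neuron_summary.csv", index=False)
    pd.concat(tables.values()).to_csv(out / "descriptor_tables.csv", index=False)
    if dist_rows:
        pd.concat(dist_rows).to_csv(out / "length_area_distributions.csv", index=False)

    # ---- comparison statistics -------------------------------------------
    alpha = cfg["statistics"]["alpha"]
    posthoc_test = cfg["statistics"]["posthoc_test"]
    stat_rows, pct_rows = [], []
    descriptors = [
        d for d in COMPARED_DESCRIPTORS
        if include_epsp or d not in ("rise_10_90", "half_width")
    ]
    for descriptor in descriptors:
        for arbor in ("apical", "basal"):
            reports_by_scale: dict[str, list[comparison.StatReport]] = {
                "absolute": [], "normalized": []
            }
            for mode in ("distance_dependence", "surface_distribution"):
                for scale in ("absolute", "normalized"):
                    try:
                        g = comparison.build_graph(
                            tables, group_of, mode, scale, descriptor, arbor
                        )
                        rep = comparison.evaluate_graph(
                            g, alpha=alpha, posthoc_test=posthoc_test
                        )
                    except (ValueError, comparison.DegenerateDataError) as exc:
                        log.warning(
                            "graph %s/%s/%s/%s skipped: %s",
                            descriptor, arbor, mode, scale, exc,
                        )
                        continue
                    reports_by_scale[scale].append(rep)
                    stat_rows.append(
                        {
                            "descriptor": descriptor,
                            "arbor": arbor,
                            "mode": mode,
                            "scale": scale,
                            **rep.anova,
                            "n_eligible_bins": rep.n_eligible,
                            "n_significant_bins": rep.n_flagged,
                        }
                    )
            for scale, reps in reports_by_scale.items():
                if reps:
                    pct_rows.append(
                        {
                            "descriptor": descriptor,
                            "arbor": arbor,
                            "scale": scale,
                            "percent_significant": comparison.percent_significant(reps),
                        }
                    )
            all_reps = reports_by_scale["absolute"] + reports_by_scale["normalized"]
            if all_reps:
                pct_rows.append(
                    {
                        "descriptor": descriptor,
                        "arbor": arbor,
                        "scale": "combined",
                        "percent_significant": comparison.percent_significant(all_reps),
                    }
                )
    pd.DataFrame(stat_rows).to_csv(out / "comparison_stats.csv", index=False)
    pd.DataFrame(pct_rows).to_csv(out / "percent_significant.csv", index=False)

    # scalar Mann–Whitney comparisons (fitted constants, predictors, means)
    mw_rows = []
    wt = summary[summary["group"] == "WT"]
    tg = summary[summary["group"] == "TG"]
    scalar_cols = [c for c in summary.columns if c not in ("neuron", "group")]
    for col in scalar_cols:
        x, y = wt[col].dropna(), tg[col].dropna()
        if len(x) >= 2 and len(y) >= 2:
            mw_rows.append(
                {
                    "quantity": col,
                    "wt_mean": float(x.mean()),
                    "tg_mean": float(y.mean()),
                    "p_mannwhitney": comparison.mann_whitney(x, y),
                }
            )
    for col in ("Rm", "Cm"):
        x = fits.loc[fits["group"] == "WT", col]
        y = fits.loc[fits["group"] == "TG", col]
        mw_rows.append(
            {
                "quantity": f"specific_{col}",
                "wt_mean": float(x.mean()),
                "tg_mean": float(y.mean()),
                "p_mannwhitney": comparison.mann_whitney(x, y),
            }
        )
    pd.DataFrame(mw_rows).to_csv(out / "scalar_comparisons.csv", index=False)

    manifest = {
        "package_version": taucable.__version__,
        "seed": cfg["seed"],
        "config": cfg,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()
        ).hexdigest(),
        "n_neurons": len(tables),
        "elapsed_s": round(time.time() - t0, 2),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out


def report(run_dir: str | Path) -> str:
    """Markdown summary of a finished run (idempotent)."""
    run = Path(run_dir)
    if not (run / "manifest.json").exists():
        raise FileNotFoundError(f"{run} is not a finished run directory")
    manifest = json.loads((run / "manifest.json").read_text())
    scalars = pd.read_csv(run / "scalar_comparisons.csv")
    pct = pd.read_csv(run / "percent_significant.csv")
    lines = [
        "# taucable run report",
        "",
        f"package {manifest['package_version']}, seed {manifest['seed']}, "
        f"{manifest['n_neurons']} neurons, {manifest['elapsed_s']} s",
        "",
        "## Group scalar comparisons (Mann–Whitney)",
        "",
        scalars.to_markdown(index=False, floatfmt=".4g"),
        "",
        "## Percent of eligible intervals with significant WT/TG differences",
        "",
        pct.to_markdown(index=False, floatfmt=".1f"),
        "",
    ]
    text = "\n".join(lines)
    (run / "report.md").write_text(text)
    return text
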