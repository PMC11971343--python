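"""Stage runner: ties the analysis stages into reproducible pipelines.

Each stage reads delimited-text inputs, runs one analysis, writes its
outputs as tables under the report directory, and contributes fitted
parameters (with uncertainties) to a machine-readable JSON summary. The
log records the seed, package versions, and thresholds used.
"""
from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import binding, nmr, stability, wham
from .config import AnalysisConfig
from .io import load_table, write_table

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs are retained."""


def _stage_fit_titration(config: AnalysisConfig, params: dict, outdir: Path) -> dict:
    df = load_table(params["input"], {"g_tot_M": float, "p_tot_M": float,
                                      "mean_E": float})
    se = df["se_E"].to_numpy() if "se_E" in df.columns else None
    series = binding.TitrationSeries(df["g_tot_M"], df["p_tot_M"],
                                     df["mean_E"], se_e=se,
                                     mode=params.get("mode", "excess"))
    fit = binding.fit_titration(series, model=params.get("model", "1:1"),
                                alpha=params.get("alpha"))
    out = {"kd_M": fit.kd_, "kd_se_M": fit.kd_se_, "e0": fit.e0_,
           "e0_se": fit.e0_se_, "de_sat": fit.de_sat_,
           "de_sat_se": fit.de_sat_se_}
    write_table(pd.DataFrame({"param": list(out), "value": [np.ravel(v)[0] if np.ndim(v)
                                                            else v for v in out.values()]}),
                outdir / "titration_fit.tsv")
    return out


def _stage_fit_salt(config: AnalysisConfig, params: dict, outdir: Path) -> dict:
    df = load_table(params["input"], {"ionic_strength_M": float, "kd_M": float})
    se = df["se_kd_M"].to_numpy() if "se_kd_M" in df.columns else None
    series = binding.SaltSeries(df["ionic_strength_M"], df["kd_M"], se_kd=se)
    fit = binding.fit_salt_dependence(series)
    out = {"n_ions_released": fit.n_ions_, "n_ions_se": fit.n_ions_se_,
           "ci90_low": fit.ci90_[0], "ci90_high": fit.ci90_[1],
           "intercept_log10": fit.intercept_}
    write_table(pd.DataFrame([out]), outdir / "salt_fit.tsv")
    return out


def _stage_bursts(config: AnalysisConfig, params: dict, outdir: Path) -> dict:
    df = load_table(params["input"], {"n_A": float, "n_D": float})
    out_df = binding.burst_efficiencies(df, config.corrections,
                                        s_window=tuple(params.get("s_window",
                                                                  (0.2, 0.75))))
    write_table(out_df, outdir / "burst_efficiencies.tsv")
    return {"n_selected": out_df.attrs["n_selected"],
            "n_dropped_empty": out_df.attrs["n_dropped_empty"],
            "mean_E": float(out_df["E"].mean())}


def _stage_csp(config: AnalysisConfig, params: dict, outdir: Path) -> dict:
    schema = {"residue": int, "delta_H_ppm": float, "delta_N_ppm": float}
    free = load_table(params["free"], schema)
    bound = load_table(params["bound"], schema)
    csp = nmr.compute_csp(free, bound)
    write_table(csp, outdir / "csp.tsv")
    return {"csp_sum_ppm": float(csp["csp_ppm"].sum()),
            "n_residues": int(len(csp)),
            "n_missing": len(csp.attrs["missing_residues"])}


def _stage_melt_fit(config: AnalysisConfig, params: dict, outdir: Path) -> dict:
    df = load_table(params["input"], {"x": float, "signal": float})
    se = df["se"].to_numpy() if "se" in df.columns else None
    curve = stability.CDCurve(df["x"], df["signal"], mode="thermal", se=se)
    fit = stability.fit_thermal_melt(curve)
    out = {"t_m_K": fit.t_m_, "t_m_se_K": fit.t_m_se_, "dh_kj": fit.dh_kj_,
           "dh_se_kj": fit.dh_kj_se_}
    write_table(pd.DataFrame([out]), outdir / "melt_fit.tsv")
    return out


def _stage_wham(config: AnalysisConfig, params: dict, outdir: Path) -> dict:
    df = load_table(params["input"], {"window_id": int, "center_nm": float,
                                      "k_kJ_mol_nm2": float, "sample_nm": float})
    windows = [wham.UmbrellaWindow(g["center_nm"].iloc[0],
                                   g["k_kJ_mol_nm2"].iloc[0],
                                   g["sample_nm"].to_numpy())
               for _, g in df.groupby("window_id")]
    uset = wham.UmbrellaSet(windows, params.get("temperature",
                                                config.temperature))
    pmf = wham.wham_pmf(uset, n_bins=params.get("n_bins", 100))
    write_table(pd.DataFrame({"r_nm": pmf.r, "W_kT": pmf.w_kt,
                              "se": pmf.se_kt}), outdir / "pmf.tsv")
    kd, kd_se = wham.kd_from_pmf(pmf, params.get("bound_cutoff"),
                                 seed=config.random_seed)
    return {"kd_M": kd, "kd_se_M": kd_se, "pmf_min_kT": float(pmf.w_kt.min())}


STAGES = {
    "fit-titration": _stage_fit_titration,
    "fit-salt": _stage_fit_salt,
    "bursts": _stage_bursts,
    "csp": _stage_csp,
    "melt-fit": _stage_melt_fit,
    "wham": _stage_wham,
}


def run_pipeline(config: AnalysisConfig, stages: list, outdir) -> dict:
    """Run a list of (stage_name, params) pairs and write a report bundle.

    A stage failure aborts the run with the failing stage named;
    outputs of completed stages are retained on disk.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    import dynacomplex
    report = {"config": config.to_dict(), "seed": config.random_seed,
              "versions": {"dynacomplex": dynacomplex.__version__,
                           "numpy": np.__version__},
              "stages": {}}
    for name, params in stages:
        if name not in STAGES:
            raise KeyError(f"unknown pipeline stage {name!r}; "
                           f"known: {sorted(STAGES)}")
        logger.info("running stage %s with params %s", name, params)
        try:
            report["stages"][name] = STAGES[name](config, params, outdir)
        except Exception as exc:
            (outdir / "report.json").write_text(json.dumps(report, indent=2,
                                                           default=float))
            raise StageError(f"stage {name!r} failed: {exc}") from exc
    (outdir / "report.json").write_text(json.dumps(report, indent=2,
                                                   default=float))
    return report
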