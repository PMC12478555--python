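"""Command-line entry points, data I/O and logging.

The CLI is a thin layer over the library: ``fit`` estimates a GPLM from a
delimited file, ``simulate`` runs the Monte-Carlo battery, ``bandwidth``
exports an EBBS diagnostic trace and ``bound`` evaluates the efficiency
bound by Monte Carlo.  Every run echoes its resolved configuration (JSON)
next to the outputs for reproducibility.
"""

from __future__ import annotations

import json
import logging
import sys
from pathlib import Path
from typing import Optional, Sequence

import click
import numpy as np
import pandas as pd

from .bandwidth import EbbsConfig, ebbs_select
from .beta_profile import fit_gplm
from .inference import efficiency_bound_mc
from .model_core import FitConfig, ObservedData
from .nuisance import LinearDelta, LogisticPi
from .simulation import SCENARIOS, SimConfig, run_battery

logger = logging.getLogger("aipwgplm")

__all__ = ["read_dataset", "write_dataset", "main", "cli"]


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_dataset(path, colmap: dict) -> ObservedData:
    """Read an :class:`ObservedData` from delimited text.

    ``colmap`` maps roles to column names: required keys ``y``, ``x``
    (list), ``z``; optional ``r`` and ``u`` (list).  Empty cells / NA mark a
    missing outcome; when no ``r`` column is given, R is derived as the
    indicator of a nonmissing y.  An explicit ``r`` column inconsistent with
    the y missingness is a hard error.
    """
    df = pd.read_csv(path)
    needed = [colmap["y"], colmap["z"], *colmap["x"], *colmap.get("u", [])]
    if colmap.get("r"):
        needed.append(colmap["r"])
    missing_cols = [c for c in needed if c not in df.columns]
    if missing_cols:
        raise ValueError(f"missing columns in {path}: {missing_cols}")
    y = pd.to_numeric(df[colmap["y"]], errors="raise").to_numpy(dtype=float)
    if colmap.get("r"):
        r = df[colmap["r"]].to_numpy()
        bad = np.nonzero((r == 1) & ~np.isfinite(y))[0]
        if bad.size:
            raise ValueError(
                f"r=1 but y is missing at rows {bad.tolist()[:20]}")
    else:
        r = np.isfinite(y).astype(int)
    if np.isfinite(y).sum() == 0:
        raise ValueError("all outcomes are missing")
    x = df[list(colmap["x"])].to_numpy(dtype=float)
    z = df[colmap["z"]].to_numpy(dtype=float)
    u = df[list(colmap["u"])].to_numpy(dtype=float) if colmap.get("u") else None
    data = ObservedData(y=y, r=r, x=x, z=z, u=u)
    logger.info("read %d rows from %s (missing outcome fraction %.3f)",
                data.n, path, data.missing_fraction)
    return data


def write_dataset(data: ObservedData, path, colmap: Optional[dict] = None) -> None:
    """Write an ObservedData back to CSV (NA for missing outcomes)."""
    colmap = colmap or {"y": "y", "r": "r", "z": "z",
                        "x": [f"x{j+1}" for j in range(data.p)],
                        "u": [f"u{j+1}" for j in range(data.u.shape[1])]}
    out = {colmap["y"]: np.where(data.r == 1, data.y, np.nan),
           colmap["r"]: data.r}
    for j, name in enumerate(colmap["x"]):
        out[name] = data.x[:, j]
    out[colmap["z"]] = data.z
    for j, name in enumerate(colmap.get("u", [])):
        out[name] = data.u[:, j]
    pd.DataFrame(out).to_csv(path, index=False)


def _echo_config(outdir: Path, name: str, payload: dict) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / f"{name}_config.json", "w") as fh:
        json.dump(payload, fh, indent=2, default=str)


def _load_config_file(path) -> dict:
    if path is None:
        return {}
    import yaml
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise click.UsageError("config file must be a flat key-value mapping")
    return cfg


# ---------------------------------------------------------------------------
# CLI
# ---------------------------------------------------------------------------


@click.group()
@click.option("-v", "--verbose", count=True, help="-v info, -vv debug")
def cli(verbose: int) -> None:
    """Doubly robust kernel-profile estimation for partially linear models."""
    level = logging.WARNING - 10 * min(verbose, 2)
    logging.basicConfig(level=level, format="%(levelname)s %(name)s: %(message)s")


@cli.command()
@click.option("--input", "input_path", required=True, type=click.Path(exists=True))
@click.option("--y", required=True)
@click.option("--r", default=None)
@click.option("--x", required=True, help="comma-separated covariate columns")
@click.option("--z", required=True)
@click.option("--u", default="", help="comma-separated auxiliary columns")
@click.option("--estimator", type=click.Choice(["naive", "ipw", "aipw"]),
              default="aipw")
@click.option("--link", type=click.Choice(["identity", "logit", "log"]),
              default="identity")
@click.option("--kernel", type=click.Choice(["epanechnikov", "gaussian"]),
              default="epanechnikov")
@click.option("--bandwidth", default="ebbs",
              help="numeric bandwidth or 'ebbs'")
@click.option("--pi-cols", default=None,
              help="columns of the logistic selection model (intercept added)")
@click.option("--delta-cols", default=None,
              help="columns of the linear outcome model (intercept added)")
@click.option("--output-dir", default=".", type=click.Path())
@click.option("--config", "config_file", default=None, type=click.Path(exists=True),
              help="flat YAML config; command-line flags win")
def fit(input_path, y, r, x, z, u, estimator, link, kernel, bandwidth,
        pi_cols, delta_cols, output_dir, config_file):
    """Fit the GPLM on a delimited dataset and export the results."""
    file_cfg = _load_config_file(config_file)
    bandwidth = file_cfg.get("bandwidth", bandwidth)
    colmap = {"y": y, "r": r, "x": x.split(","), "z": z,
              "u": [c for c in u.split(",") if c]}
    data = read_dataset(input_path, colmap)
    df = pd.read_csv(input_path)

    def cols_design(names):
        mat = df[names.split(",")].to_numpy(dtype=float)
        return np.column_stack([np.ones(len(mat)), mat])

    pi_spec = None
    if estimator in ("ipw", "aipw"):
        if pi_cols is None:
            raise click.UsageError("--pi-cols is required for ipw/aipw")
        pi_spec = LogisticPi(cols_design(pi_cols),
                             names=["intercept", *pi_cols.split(",")])
    delta_spec = None
    if estimator == "aipw":
        if delta_cols is None:
            raise click.UsageError("--delta-cols is required for aipw")
        delta_spec = LinearDelta(cols_design(delta_cols),
                                 names=["intercept", *delta_cols.split(",")])
    bw = bandwidth if bandwidth == "ebbs" else float(bandwidth)
    fc = FitConfig(estimator=estimator, link=link, kernel=kernel, bandwidth=bw,
                   pi_spec=pi_spec, delta_spec=delta_spec)
    fit_res = fit_gplm(data, fc)

    outdir = Path(output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    fit_res.summary_frame().to_csv(outdir / "coefficients.csv")
    curve = pd.DataFrame({
        "z": fit_res.theta.z_eval,
        "theta_hat": fit_res.theta.alpha0,
        "slope": fit_res.theta.alpha1,
        "se": fit_res.theta.se if fit_res.theta.se is not None else np.nan,
    })
    for j in range(data.p):
        curve[f"phi_{j+1}"] = fit_res.theta.phi[:, j]
    curve.to_csv(outdir / "theta_curve.csv", index=False)
    _echo_config(outdir, "fit", {
        "input": str(input_path), "colmap": colmap, "estimator": estimator,
        "link": link, "kernel": kernel, "bandwidth": fit_res.h,
        "pi_cols": pi_cols, "delta_cols": delta_cols,
        "converged": fit_res.converged, "n_outer": fit_res.n_outer,
    })
    click.echo(fit_res.summary_frame().to_string())


@cli.command()
@click.option("--n", default=500, show_default=True)
@click.option("--reps", default=100, show_default=True)
@click.option("--seed", default=0, show_default=True)
@click.option("--scenarios", default="all",
              help="comma-separated scenario names or 'all'")
@click.option("--bandwidth", default=0.15, show_default=True, type=float)
@click.option("--output-dir", default=".", type=click.Path())
def simulate(n, reps, seed, scenarios, bandwidth, output_dir):
    """Run the two-stage-design Monte-Carlo battery."""
    names = sorted(SCENARIOS) if scenarios == "all" else scenarios.split(",")
    cfg = SimConfig(n=n, reps=reps, seed=seed)
    fc = FitConfig(estimator="naive", link="identity", bandwidth=bandwidth)
    report = run_battery(cfg, names, fc)
    outdir = Path(output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    frame = report.to_frame()
    frame.to_csv(outdir / "sim_report.csv")
    _echo_config(outdir, "simulate", {
        "n": n, "reps": reps, "seed": seed, "scenarios": names,
        "bandwidth": bandwidth,
        "median_missing_fraction": report.median_missing_fraction,
    })
    click.echo(frame.to_string())


@cli.command()
@click.option("--n", default=500, show_default=True)
@click.option("--seed", default=0, show_default=True)
@click.option("--estimator", type=click.Choice(["naive", "ipw", "aipw"]),
              default="aipw")
@click.option("--output-dir", default=".", type=click.Path())
def bandwidth(n, seed, estimator, output_dir):
    """EBBS bandwidth trace on one simulated dataset."""
    from .nuisance import fit_missingness, fit_outcome_model, fit_working_variance, initial_fit
    from .simulation import generate_dataset, scenario_config

    cfg = SimConfig(n=n, seed=seed)
    data, _ = generate_dataset(cfg, 0)
    scen = {"naive": "naive", "ipw": "ipw-fitted-pi",
            "aipw": "aipw-fitted-both"}[estimator]
    fc = scenario_config(scen, cfg, FitConfig(link="identity", bandwidth=0.15))
    fit_res = fit_gplm(data, fc)
    ebbs_cfg = EbbsConfig.default(data.z)
    h_opt, h_global, trace = ebbs_select(data, fit_res.nuis, fit_res.beta_hat,
                                         fc, ebbs_cfg, return_trace=True)
    outdir = Path(output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    trace.to_csv(outdir / "ebbs_trace.csv", index=False)
    _echo_config(outdir, "bandwidth", {
        "n": n, "seed": seed, "estimator": estimator,
        "h_opt": h_opt.tolist(), "h_global": h_global,
    })
    click.echo(f"selected global bandwidth: {h_global:.4f}")


@cli.command()
@click.option("--n-outer", default=100_000, show_default=True)
@click.option("--n-inner", default=200, show_default=True)
@click.option("--seed", default=0, show_default=True)
@click.option("--output-dir", default=".", type=click.Path())
def bound(n_outer, n_inner, seed, output_dir):
    """Monte-Carlo semiparametric efficiency bound for the simulated design."""
    cfg = SimConfig()
    res = efficiency_bound_mc(cfg, n_outer=n_outer, n_inner=n_inner, seed=seed)
    outdir = Path(output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({
        "v_eff": [float(res.v_eff[0, 0])],
        "mc_se": [float(res.mc_se[0, 0])],
        "mc_draws": [res.mc_draws],
    }).to_csv(outdir / "efficiency_bound.csv", index=False)
    _echo_config(outdir, "bound", {"n_outer": n_outer, "n_inner": n_inner,
                                   "seed": seed,
                                   "v_eff": float(res.v_eff[0, 0])})
    click.echo(f"V_eff = {res.v_eff[0, 0]:.4f} (MC se {res.mc_se[0, 0]:.4f})")


def main(argv: Optional[Sequence[str]] = None) -> int:
    try:
        cli.main(args=argv, standalone_mode=False)
    except click.ClickException as exc:
        exc.show()
        return exc.exit_code
    except SystemExit as exc:  # pragma: no cover
        return int(exc.code or 0)
    return 0


if __name__ == "__main__":
    sys.exit(main())
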