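"""End-to-end orchestration: simulate -> ensemble -> DAH -> scenarios ->
frontier -> report.

A single root seed drives every stage; per-stage substreams are derived by
hashing the stage name together with the seed, so adding a stage never shifts
the randomness of the others and two runs with the same config are
bit-identical.  Every stage writes self-describing CSV artifacts (a ``#``
metadata block with the stage name and a config hash); on resumption a stage
is skipped when all of its artifacts are present with a matching hash and no
upstream stage was re-run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import warnings
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import aggregate as agg
from . import dah as dah_mod
from . import ensemble as ens
from . import frontier as fr
from . import scenarios as sc
from .draws import DrawSet
from .errors import ConfigError, FitError, PoolingError
from .panel import POOLED_COMPONENTS, read_panel, total_spend_pc, validate_panel
from .synth import GeneratorConfig, generate_dah_network, generate_panel

log = logging.getLogger("healthcast.pipeline")

STAGES = ["simulate", "ensemble", "dah", "scenarios", "frontier", "report"]


def derive_seed(seed: int, stage: str) -> int:
    """Stable per-stage substream seed (< 2^31)."""
    return zlib.crc32(f"{stage}:{seed}".encode()) % (2**31)


@dataclass
class PipelineConfig:
    """Settings for a full pipeline run."""

    out_dir: str = "healthcast_out"
    seed: int = 0
    horizon: int = 2040
    n_draws: int = 1000
    input_panel: str | None = None           # if None, simulate
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    percentile_better: float = 85.0
    percentile_worse: float = 15.0
    holdout_years: int = 5
    covariate_subsets: list[list[str]] = field(
        default_factory=lambda: [
            ["convergence_term"],
            ["education_years", "convergence_term"],
            ["education_years", "tfr", "convergence_term"],
            ["frac_under20", "frac_over65", "convergence_term"],
        ]
    )
    weight_schemes: list[str] = field(default_factory=lambda: ["equal", "decay10"])
    ar_orders: list[int] = field(default_factory=lambda: [0, 1])
    ma_orders: list[int] = field(default_factory=lambda: [0])
    frontier_per_draw: bool = False
    decomposition_mid_year: int = 2030

    def __post_init__(self):
        if self.n_draws < 2:
            raise ConfigError("n_draws must be at least 2 (>= 1000 for full-fidelity runs)")
        if isinstance(self.generator, dict):
            self.generator = GeneratorConfig(**self.generator)

    # -- presets -----------------------------------------------------------
    @classmethod
    def fast(cls, out_dir: str, seed: int = 0, **overrides) -> "PipelineConfig":
        """Small world for development and smoke runs: 20 countries, 100
        draws, a compact grid, single frontier fit."""
        gen = GeneratorConfig(n_countries=20, seed=derive_seed(seed, "world"))
        defaults = dict(
            out_dir=out_dir, seed=seed, n_draws=100, generator=gen,
            covariate_subsets=[["convergence_term"], ["education_years", "convergence_term"]],
            weight_schemes=["equal", "decay10"], ar_orders=[0, 1], ma_orders=[0],
            frontier_per_draw=False,
        )
        defaults.update(overrides)
        return cls(**defaults)

    @classmethod
    def full_fidelity(cls, out_dir: str, seed: int = 0, **overrides) -> "PipelineConfig":
        """188 countries, 1000 draws, per-draw frontier parameter sampling."""
        gen = GeneratorConfig(n_countries=188, seed=derive_seed(seed, "world"))
        defaults = dict(out_dir=out_dir, seed=seed, n_draws=1000, generator=gen,
                        frontier_per_draw=True)
        defaults.update(overrides)
        return cls(**defaults)

    # -- (de)serialisation -------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        gen = data.pop("generator", None)
        cfg = cls(**data)
        if gen is not None:
            share_params = gen.pop("share_params", None)
            from .synth import ShareParams, _default_share_params

            params = _default_share_params() if share_params is None else {
                k: ShareParams(**v) for k, v in share_params.items()
            }
            cfg.generator = GeneratorConfig(**gen, share_params=params)
        return cfg

    def config_hash(self) -> str:
        """Hash of every setting that affects the computed numbers.

        The output directory is a storage location, not a modelling choice,
        so it is excluded: runs in different directories with the same
        settings produce identical artifacts.
        """
        d = self.to_dict()
        d.pop("out_dir", None)
        text = yaml.safe_dump(d, sort_keys=True)
        return hashlib.md5(text.encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# artifact helpers
# ---------------------------------------------------------------------------

def _write_artifact(frame: pd.DataFrame, path: Path, stage: str, cfg_hash: str,
                    index: bool = False) -> None:
    with open(path, "w") as fh:
        fh.write(f"# healthcast stage={stage}\n# config_hash={cfg_hash}\n")
        frame.to_csv(fh, index=index)


def _artifact_hash(path: Path) -> str | None:
    try:
        with open(path) as fh:
            for line in fh:
                if line.startswith("# config_hash="):
                    return line.strip().split("=", 1)[1]
                if not line.startswith("#"):
                    break
    except OSError:
        return None
    return None


def _read_artifact(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


_STAGE_ARTIFACTS = {
    "simulate": ["panel.csv", "dah_sources.csv", "dah_shares.csv"],
    "ensemble": ["spending_draws.csv", "model_report.csv"],
    "dah": ["dah_draws.csv"],
    "scenarios": ["scenarios.csv"],
    "frontier": ["frontier_params.csv", "frontier_gaps.csv", "uhc_projection.csv"],
    "report": ["report_groups.csv", "decomposition.csv", "lives_covered.csv"],
}


def _stage_complete(out: Path, stage: str, cfg_hash: str) -> bool:
    return all(
        (out / name).exists() and _artifact_hash(out / name) == cfg_hash
        for name in _STAGE_ARTIFACTS[stage]
    )


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_simulate(config: PipelineConfig, out: Path, cfg_hash: str, state: dict) -> dict:
    if config.input_panel is not None:
        panel = read_panel(config.input_panel)
        network = generate_dah_network(config.generator, panel)
    else:
        panel = generate_panel(config.generator)
        network = generate_dah_network(config.generator, panel)
    _write_artifact(panel, out / "panel.csv", "simulate", cfg_hash)
    _write_artifact(network.sources, out / "dah_sources.csv", "simulate", cfg_hash)
    _write_artifact(network.recipient_shares, out / "dah_shares.csv", "simulate", cfg_hash)
    return {"panel": panel, "network": network}


def _load_simulate(config: PipelineConfig, out: Path) -> dict:
    panel = validate_panel(_read_artifact(out / "panel.csv"))
    network = dah_mod.DahNetwork(
        sources=_read_artifact(out / "dah_sources.csv"),
        recipient_shares=_read_artifact(out / "dah_shares.csv").rename(
            columns={"country_id": "country"}
        ),
        transition_threshold=config.generator.transition_threshold,
    )
    return {"panel": panel, "network": network}


def _stage_ensemble(config: PipelineConfig, out: Path, cfg_hash: str, state: dict) -> dict:
    panel = state["panel"]
    seed = derive_seed(config.seed, "ensemble")
    draws_by_target: dict[str, DrawSet] = {}
    reports = []
    for target in ens.TARGETS:
        grid = ens.build_model_grid(
            config.covariate_subsets, config.weight_schemes,
            config.ar_orders, config.ma_orders, target,
        )
        fits = []
        for spec in grid:
            try:
                fits.append(ens.fit_candidate(panel, spec, holdout_years=config.holdout_years))
            except FitError as exc:
                reports.append({"target": target, "spec": repr(spec), "retained": False,
                                "reason": f"fit_error: {exc}"})
        bounds = ens.historical_growth_bounds(panel, target)
        retained, report = ens.apply_exclusion_rules(fits, bounds)
        report.insert(0, "target", target)
        reports.append(report)
        if not retained:
            warnings.warn(f"{target}: all candidates excluded; "
                          "falling back to intercept + convergence model")
            retained = [ens.intercept_convergence_fallback(panel, target,
                                                           holdout_years=config.holdout_years)]
        growth_draws = ens.rank_and_pool(
            retained, panel, config.n_draws, config.horizon,
            seed=derive_seed(seed, target),
        )
        weights = ens.pooling_weights(retained)
        sd = sum(
            w * f.oos_sd_by_country.reindex(growth_draws.countries).fillna(0.0)
            for w, f in zip(weights, retained)
        )
        # white-noise increments on the growth scale: once the chain cumulates
        # growth into levels, the level path carries the first-order random walk
        growth_draws = ens.add_random_walk_noise(
            growth_draws, sd, seed=derive_seed(seed, f"noise:{target}"),
            cumulative=False,
        )
        draws_by_target[target] = growth_draws
    level_draws = ens.project_chain(panel, draws_by_target, config.horizon)
    report_frame = pd.concat(
        [r if isinstance(r, pd.DataFrame) else pd.DataFrame([r]) for r in reports],
        ignore_index=True,
    )
    long = level_draws.frame.stack()
    long.index = long.index.set_names(["country", "year", "quantity", "draw"])
    _write_artifact(long.rename("value").reset_index(), out / "spending_draws.csv",
                    "ensemble", cfg_hash)
    _write_artifact(report_frame, out / "model_report.csv", "ensemble", cfg_hash)
    return {"level_draws": level_draws, "model_report": report_frame}


def _load_ensemble(config: PipelineConfig, out: Path) -> dict:
    long = _read_artifact(out / "spending_draws.csv")
    wide = long.pivot_table(index=["country", "year", "quantity"], columns="draw",
                            values="value")
    return {"level_draws": DrawSet(wide),
            "model_report": _read_artifact(out / "model_report.csv")}


def _stage_dah(config: PipelineConfig, out: Path, cfg_hash: str, state: dict) -> dict:
    panel, network = state["panel"], state["network"]
    level_draws = state["level_draws"]
    seed = derive_seed(config.seed, "dah")
    last_year = int(panel["year"].max())
    horizon_years = config.horizon - last_year
    forecast_years = list(range(last_year + 1, config.horizon + 1))

    provided_parts = []
    for sid in sorted(network.sources["source_id"].unique()):
        src = network.source_series(sid)
        if src.kind == "state":
            provided_parts.append(dah_mod.project_source_dah(src, level_draws))
        else:
            provided_parts.append(
                dah_mod.forecast_nonstate_source(
                    src.amounts, horizon_years, order=None,
                    n_draws=config.n_draws, seed=derive_seed(seed, sid),
                    source_id=sid, first_forecast_year=last_year + 1,
                )
            )
    provided = DrawSet.concat(provided_parts)
    totals = provided.frame.groupby(level="year").sum()
    totals = np.maximum(totals, 0.0)  # donors cannot provide negative assistance
    total_draws = DrawSet(
        pd.DataFrame(
            totals.to_numpy(),
            index=pd.MultiIndex.from_product(
                [["__world__"], list(totals.index), ["dah_total"]],
                names=["country", "year", "quantity"],
            ),
        )
    )

    # recipient shares: hold the last observed year's shares constant forward
    last_shares = network.recipient_shares[
        network.recipient_shares["year"] == network.recipient_shares["year"].max()
    ]
    future_shares = pd.concat(
        [last_shares.assign(year=y) for y in forecast_years], ignore_index=True
    )
    allocated = dah_mod.allocate_recipient_dah(total_draws, future_shares)
    transitioned = dah_mod.apply_income_transition(
        allocated, level_draws, threshold=network.transition_threshold
    )

    # convert currency to per-capita using projected populations
    arr, countries, years = transitioned.array("dah")
    pop = ens._project_population(panel, years).loc[countries].to_numpy()[:, :, None]
    dah_pc = DrawSet.from_array(arr / pop, countries, years, "dah_pc")
    long = dah_pc.frame.stack()
    long.index = long.index.set_names(["country", "year", "quantity", "draw"])
    _write_artifact(long.rename("value").reset_index(), out / "dah_draws.csv", "dah", cfg_hash)
    return {"dah_pc_draws": dah_pc}


def _load_dah(config: PipelineConfig, out: Path) -> dict:
    long = _read_artifact(out / "dah_draws.csv")
    wide = long.pivot_table(index=["country", "year", "quantity"], columns="draw",
                            values="value")
    return {"dah_pc_draws": DrawSet(wide)}


def _reference_components(state: dict) -> pd.DataFrame:
    """Draw-mean reference trajectories per component (per capita)."""
    level_draws, dah_pc = state["level_draws"], state["dah_pc_draws"]
    means = level_draws.mean().rename("reference").reset_index()
    comp = means[means["quantity"].isin(["ghes_pc", "ppp_pc", "oop_pc"])]
    dah_means = dah_pc.mean().rename("reference").reset_index()
    comp = pd.concat([comp, dah_means], ignore_index=True)
    # countries that never receive DAH contribute zero rows
    full = (
        comp.pivot_table(index=["country", "year"], columns="quantity",
                         values="reference", fill_value=0.0)
        .reindex(columns=["ghes_pc", "ppp_pc", "oop_pc", "dah_pc"], fill_value=0.0)
        .stack()
        .rename("reference")
        .reset_index()
        .rename(columns={"quantity": "component"})
    )
    return full


def _stage_scenarios(config: PipelineConfig, out: Path, cfg_hash: str, state: dict) -> dict:
    panel = state["panel"]
    last_year = int(panel["year"].max())
    components = _reference_components(state)
    ref_totals = (
        components.groupby(["country", "year"])["reference"].sum().reset_index()
    )

    growth = sc.compute_longterm_growth(panel)
    baseline = panel[panel["year"] == int(panel["year"].min())].set_index("country_id")
    conv = np.log(total_spend_pc(baseline))
    reg = sc.fit_convergence_regression(
        growth, conv,
        percentile_better=config.percentile_better,
        percentile_worse=config.percentile_worse,
    )
    last = panel[panel["year"] == last_year].set_index("country_id")
    baseline_levels = total_spend_pc(last)
    scen_totals = sc.build_alternative_scenarios(reg, ref_totals, baseline_levels, last_year)
    scen_totals = sc.clip_to_reference(scen_totals)
    scen_components = sc.scale_components(scen_totals, components)
    full = pd.concat([scen_totals.frame, scen_components.frame], ignore_index=True)
    full = full.sort_values(["country", "year", "component"]).reset_index(drop=True)
    _write_artifact(full, out / "scenarios.csv", "scenarios", cfg_hash)
    return {"scenarios": sc.ScenarioSet(full)}


def _load_scenarios(config: PipelineConfig, out: Path) -> dict:
    return {"scenarios": sc.ScenarioSet(_read_artifact(out / "scenarios.csv"))}


def _pooled_scenarios(scen: sc.ScenarioSet) -> sc.ScenarioSet:
    comp = scen.frame[scen.frame["component"].isin(["ghes_pc", "ppp_pc", "dah_pc"])]
    pooled = (
        comp.groupby(["country", "year"])[["reference", "better", "worse"]]
        .sum()
        .reset_index()
    )
    pooled["component"] = "pooled"
    return sc.ScenarioSet(pooled)


def _stage_frontier(config: PipelineConfig, out: Path, cfg_hash: str, state: dict) -> dict:
    panel, scen = state["panel"], state["scenarios"]
    fit = fr.fit_sfa(panel)
    gaps = fr.estimate_gap_trajectory(fit, panel, config.horizon)
    pooled = _pooled_scenarios(scen)
    uhc = fr.project_uhc_index(fit, gaps, pooled)

    if config.frontier_per_draw and fit.cov_params is not None:
        # propagate frontier parameter uncertainty: one (alpha, beta) draw per
        # Monte-Carlo draw, reference-scenario UHC recomputed for each
        rng = np.random.default_rng(derive_seed(config.seed, "frontier"))
        cov = fit.cov_params[:2, :2]
        try:
            chol = np.linalg.cholesky(cov + 1e-14 * np.eye(2))
        except np.linalg.LinAlgError:
            chol = np.zeros((2, 2))
        gap_lut = gaps.frame.set_index(["country", "year"])["gap"]
        idx = pd.MultiIndex.from_frame(pooled.frame[["country", "year"]])
        gap_vals = gap_lut.reindex(idx).to_numpy()
        logx = np.log(pooled.frame["reference"].to_numpy())
        ab = np.array([fit.alpha, fit.beta])[:, None] + chol @ rng.standard_normal(
            (2, config.n_draws)
        )
        vals = np.clip(
            np.exp(ab[0][None, :] + ab[1][None, :] * logx[:, None]) * np.exp(-gap_vals)[:, None],
            0.0, 100.0,
        )
        uhc_draws = pd.DataFrame(
            vals,
            index=pd.MultiIndex.from_arrays(
                [pooled.frame["country"], pooled.frame["year"],
                 ["uhc_reference"] * len(pooled.frame)],
                names=["country", "year", "quantity"],
            ),
        )
        summary = agg.summarize_uncertainty(DrawSet(uhc_draws))
        uhc = uhc.merge(
            summary.reset_index()[["country", "year", "lower", "upper"]],
            on=["country", "year"], how="left",
        )

    params = pd.DataFrame(
        [{
            "alpha": fit.alpha, "beta": fit.beta,
            "sigma_v": fit.sigma_v, "sigma_u": fit.sigma_u,
            "loglik": fit.loglik, "n_obs": fit.n_obs,
            "pct_per_10pct": fit.elasticity_pct_per_10pct(),
        }]
    )
    _write_artifact(params, out / "frontier_params.csv", "frontier", cfg_hash)
    _write_artifact(gaps.frame, out / "frontier_gaps.csv", "frontier", cfg_hash)
    _write_artifact(uhc, out / "uhc_projection.csv", "frontier", cfg_hash)
    return {"frontier_fit": fit, "gaps": gaps, "uhc": uhc}


def _load_frontier(config: PipelineConfig, out: Path) -> dict:
    params = _read_artifact(out / "frontier_params.csv").iloc[0]
    gaps = fr.EfficiencyGapPath(_read_artifact(out / "frontier_gaps.csv"))
    uhc = _read_artifact(out / "uhc_projection.csv")
    fit = fr.FrontierFit(
        alpha=params["alpha"], beta=params["beta"], sigma_v=params["sigma_v"],
        sigma_u=params["sigma_u"], loglik=params["loglik"],
        u_hat=pd.Series(dtype=float), n_obs=int(params["n_obs"]),
    )
    return {"frontier_fit": fit, "gaps": gaps, "uhc": uhc}


def _stage_report(config: PipelineConfig, out: Path, cfg_hash: str, state: dict) -> dict:
    panel, scen, uhc, fit = (
        state["panel"], state["scenarios"], state["uhc"], state["frontier_fit"]
    )
    last_year = int(panel["year"].max())
    mid = config.decomposition_mid_year
    if not (last_year < mid < config.horizon):
        mid = (last_year + config.horizon) // 2

    labels = panel[panel["year"] == last_year][
        ["country_id", "income_group", "super_region", "population"]
    ].set_index("country_id")
    pop_proj = ens._project_population(panel, [mid, config.horizon])

    # lives covered by scenario and year
    lives_rows = []
    for year in (mid, config.horizon):
        sub = uhc[uhc["year"] == year].set_index("country")
        pop = pop_proj[year].reindex(sub.index)
        for scenario in sc.SCENARIOS:
            covered = agg.lives_covered(sub[scenario], pop)
            lives_rows.append({
                "year": year, "scenario": scenario,
                "lives_covered": float(np.sum(covered)),
                "population": float(pop.sum()),
            })
    lives = pd.DataFrame(lives_rows)

    # group-level aggregation at the horizon (reference scenario)
    sub = uhc[uhc["year"] == config.horizon].set_index("country")
    pooled = _pooled_scenarios(scen)
    pooled_ref = pooled.frame[pooled.frame["year"] == config.horizon].set_index("country")
    frame = pd.DataFrame({
        "country_id": sub.index,
        "year": config.horizon,
        "uhc_index": sub["reference"].to_numpy(),
        "pooled_pc": pooled_ref["reference"].reindex(sub.index).to_numpy(),
        "population": pop_proj[config.horizon].reindex(sub.index).to_numpy(),
    })
    frame = frame.join(labels[["income_group", "super_region"]], on="country_id")
    groups = pd.concat(
        [
            agg.aggregate_groups(frame, by=by, spend_cols=("pooled_pc",))
            .rename(columns={by: "group"})
            .assign(grouping=by)
            for by in ("income_group", "super_region")
        ],
        ignore_index=True,
    )

    # Das Gupta decomposition of reference UHC change per period, by country
    hist_last = panel[panel["year"] == last_year].set_index("country_id")
    pooled_hist = hist_last[POOLED_COMPONENTS].sum(axis=1)
    uhc_by_year = {
        y: uhc[uhc["year"] == y].set_index("country")["reference"]
        for y in (mid, config.horizon)
    }
    pooled_by_year = {
        y: pooled.frame[pooled.frame["year"] == y].set_index("country")["reference"]
        for y in (mid, config.horizon)
    }
    decomp_rows = []
    for (y0, y1) in ((last_year, mid), (mid, config.horizon)):
        u0 = hist_last["uhc_index"] if y0 == last_year else uhc_by_year[y0]
        p0 = pooled_hist if y0 == last_year else pooled_by_year[y0]
        u1, p1 = uhc_by_year[y1], pooled_by_year[y1]
        common = u0.index.intersection(u1.index)
        f0 = fr.predict_frontier(fit, p0.reindex(common).to_numpy())
        f1 = fr.predict_frontier(fit, p1.reindex(common).to_numpy())
        res = agg.decompose_das_gupta(
            u0.reindex(common).to_numpy(), u1.reindex(common).to_numpy(), f0, f1
        )
        s_share, e_share = res.shares_pct()
        decomp_rows.append(pd.DataFrame({
            "country": common,
            "period": f"{y0}-{y1}",
            "delta_total": res.delta_total,
            "delta_spending": res.delta_spending,
            "delta_efficiency": res.delta_efficiency,
            "spending_share_pct": s_share,
            "efficiency_share_pct": e_share,
        }))
    decomp = pd.concat(decomp_rows, ignore_index=True)

    _write_artifact(groups, out / "report_groups.csv", "report", cfg_hash)
    _write_artifact(decomp, out / "decomposition.csv", "report", cfg_hash)
    _write_artifact(lives, out / "lives_covered.csv", "report", cfg_hash)
    return {"groups": groups, "decomposition": decomp, "lives": lives}


_STAGE_FNS = {
    "simulate": (_stage_simulate, _load_simulate),
    "ensemble": (_stage_ensemble, _load_ensemble),
    "dah": (_stage_dah, _load_dah),
    "scenarios": (_stage_scenarios, _load_scenarios),
    "frontier": (_stage_frontier, _load_frontier),
    "report": (_stage_report, None),
}


def run_pipeline(config: PipelineConfig, force: bool = False) -> Path:
    """Run all stages in order, reusing artifacts where possible.

    A stage is recomputed when ``force`` is set, when any of its artifacts is
    missing or carries a stale config hash, or when an upstream stage was
    recomputed in this run.  Returns the output directory.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.config_hash()
    state: dict = {}
    upstream_ran = False
    for stage in STAGES:
        run_fn, load_fn = _STAGE_FNS[stage]
        complete = _stage_complete(out, stage, cfg_hash)
        if not force and not upstream_ran and complete:
            log.info("stage %s: artifacts up to date, skipping", stage)
            if load_fn is not None:
                state.update(load_fn(config, out))
            continue
        log.info("stage %s: running", stage)
        try:
            state.update(run_fn(config, out, cfg_hash, state))
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        upstream_ran = True
    return out
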