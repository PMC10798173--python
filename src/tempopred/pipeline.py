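"""End-to-end orchestration: simulate -> features -> global analysis ->
local analysis -> interplay -> rating analysis -> report.

Every stage reads and writes only declared CSV/JSON artifacts in the run
directory, records the seed it used, and logs counts (trials generated,
valid bins, clusters found) so silent filter bugs surface.  Re-running with
the same config reproduces identical checksums for the deterministic
stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, cluster_perm, glmm, history_stats, io, observer
from .sequences import ALLOWED_STDS

log = logging.getLogger("tempopred")

#: condition subsets mirroring the local-statistics analyses
SUBSETS = {
    "all_nonperiodic": (25.0, 50.0, 75.0, 100.0, 150.0),
    "low_variability": (25.0, 50.0),
    "high_variability": (75.0, 100.0, 150.0),
}

STAGES = (
    "simulate",
    "features",
    "analyze-global",
    "analyze-local",
    "analyze-interplay",
    "analyze-rating",
)


@dataclass
class RunConfig:
    seed: int = 0
    n_subjects: int = 19
    conditions: tuple = ALLOWED_STDS
    observer: observer.ObserverParams = field(default_factory=observer.ObserverParams)
    n_perm: int = 1000
    alpha_form: float = 0.05
    min_count: int = 5
    pool_n_std: tuple = (2, 3, 4, 5, 6, 7)  # matched-N pooling for the 2-D maps
    interplay_n: tuple = (2, 3, 4, 5, 6, 7)
    subsets: tuple = tuple(SUBSETS)
    measures: tuple = ("acc", "rt")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "observer" in d and isinstance(d["observer"], dict):
            d["observer"] = observer.ObserverParams(**d["observer"])
        for k in ("conditions", "pool_n_std", "interplay_n", "subsets", "measures"):
            if k in d and d[k] is not None:
                d[k] = tuple(d[k])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


# --------------------------------------------------------------------------- stages


def stage_simulate(config: RunConfig, outdir: Path) -> list[Path]:
    rng = np.random.default_rng(config.seed)
    trials, ratings = observer.simulate_cohort(
        config.n_subjects, config.observer, rng, conditions=config.conditions
    )
    if config.n_subjects < 5:
        log.warning("small cohort (n=%d): mixed-model stages will be fragile",
                    config.n_subjects)
    log.info("simulated %d trials, %d target responses, %d ratings",
             len(trials), trials["correct"].notna().sum(), len(ratings))
    tp, rp = outdir / "trials.csv", outdir / "ratings.csv"
    io.write_trials_csv(trials, tp)
    io.write_ratings_csv(ratings, rp)
    return [tp, rp]


def stage_features(config: RunConfig, outdir: Path) -> list[Path]:
    trials = io.read_trials_csv(outdir / "trials.csv")
    feats = history_stats.cohort_features(trials)
    log.info("computed history features for %d targets", len(feats))
    fp = outdir / "features.csv"
    feats.to_csv(fp, index=False)
    return [fp]


def _fit_summary(fit: glmm.MixedFit) -> dict:
    return {
        "coef": fit.coef.to_dict(),
        "se": fit.se.to_dict(),
        "random_sd": fit.random_sd,
        "aux": fit.aux,
        "loglik": fit.loglik,
        "n_obs": fit.n_obs,
        "n_groups": fit.n_groups,
        "converged": fit.converged,
        "boundary": fit.boundary,
    }


def stage_analyze_global(config: RunConfig, outdir: Path) -> list[Path]:
    feats = pd.read_csv(outdir / "features.csv")
    feats = feats.dropna(subset=["correct"])
    feats = feats.assign(global_std=feats["condition_std_ms"],
                         global_std_f=feats["condition_std_ms"].astype(str))
    results: dict = {"seed": config.seed}

    acc_spec = glmm.ModelSpec(response="correct", family="binomial", fixed=("global_std",))
    acc_fit = glmm.fit_glmm(feats, acc_spec)
    acc_slope_spec = dataclasses.replace(acc_spec, random_slope="global_std")
    acc_slope_fit = glmm.fit_glmm(feats, acc_slope_spec)
    results["accuracy"] = {
        "fit": _fit_summary(acc_fit),
        "wald_type2": glmm.wald_type2(acc_fit).to_dict("records"),
        "lrt_random_slope": dataclasses.asdict(glmm.lrt(acc_fit, acc_slope_fit)),
        "ame_per_25ms_pp": 100.0 * glmm.average_marginal_effect(acc_fit, "global_std", 25.0),
    }

    rt_spec = glmm.ModelSpec(response="rt_ms", family="gamma", link="identity",
                             fixed=("global_std",), random_slope="global_std")
    rt_fit = glmm.fit_glmm(feats, rt_spec)
    results["rt"] = {
        "fit": _fit_summary(rt_fit),
        "wald_type2": glmm.wald_type2(rt_fit).to_dict("records"),
        "slope_ms_per_25ms": 25.0 * float(rt_fit.coef["global_std"]),
    }

    acc_cat = glmm.fit_glmm(
        feats, glmm.ModelSpec(response="correct", family="binomial", factor="global_std_f")
    )
    contrasts = glmm.pairwise_tukey(acc_cat)
    cp = outdir / "contrasts_accuracy.csv"
    contrasts.to_csv(cp, index=False)

    restricted = glmm.restrict_to_mean_soa(feats)
    results["restricted_soa_500"] = {"n_targets": int(len(restricted))}
    if restricted["subject"].nunique() >= 2 and len(restricted) > 50:
        r_fit = glmm.fit_glmm(restricted, acc_spec)
        results["restricted_soa_500"]["accuracy"] = {
            "fit": _fit_summary(r_fit),
            "wald_type2": glmm.wald_type2(r_fit).to_dict("records"),
        }
    gp = outdir / "global_results.json"
    io.write_json(results, gp)
    log.info("global analysis done: AME %.3f pp / 25 ms, RT slope %.2f ms / 25 ms",
             results["accuracy"]["ame_per_25ms_pp"], results["rt"]["slope_ms_per_25ms"])
    return [gp, cp]


def _pooled_maps(feats: pd.DataFrame, config: RunConfig, measure: str):
    """Per-participant z-maps with matched-N pooling of (mean_N, std_N)."""
    zmaps = []
    participants = []
    for subject, grp in feats.groupby("subject", sort=True):
        pooled = pd.concat(
            [
                grp.rename(columns={f"mean_{n}": "mean_N", f"std_{n}": "std_N"})[
                    ["mean_N", "std_N", "correct", "rt_ms"]
                ]
                for n in config.pool_n_std
            ],
            ignore_index=True,
        )
        pooled = pooled.rename(columns={"mean_N": "mean_2", "std_N": "std_2"})
        pmap = history_stats.bin_performance_map(
            pooled, 2, 2, min_count=config.min_count
        )
        zmap = history_stats.zscore_map(pmap, field=measure)
        if zmap.valid.any():
            zmaps.append(zmap)
            participants.append(subject)
    return zmaps, participants


def stage_analyze_local(config: RunConfig, outdir: Path) -> list[Path]:
    feats = pd.read_csv(outdir / "features.csv").dropna(subset=["correct"])
    results: dict = {"seed": config.seed, "tests": []}
    for subset_name in config.subsets:
        stds = SUBSETS[subset_name]
        sub = feats[feats["condition_std_ms"].isin(stds)]
        for measure in config.measures:
            zmaps, participants = _pooled_maps(sub, config, measure)
            entry = {
                "subset": subset_name,
                "measure": measure,
                "n_participants": len(zmaps),
            }
            if len(zmaps) < 2:
                entry["skipped"] = "fewer than 2 participants with valid maps"
                results["tests"].append(entry)
                continue
            try:
                data, mask = history_stats.stack_group(zmaps)
            except ValueError as exc:
                entry["skipped"] = str(exc)
                results["tests"].append(entry)
                continue
            res = cluster_perm.permutation_test(
                data, mask, n_perm=config.n_perm, alpha_form=config.alpha_form,
                seed=config.seed,
            )
            n_sig = sum(bool(c.significant) for c in res.clusters)
            log.info("local %s/%s: %d valid bins, %d clusters (%d significant)",
                     subset_name, measure, int(mask.sum()), len(res.clusters), n_sig)
            entry.update(
                cluster_perm.result_to_records(
                    res, history_stats.MEAN_CENTERS, history_stats.STD_CENTERS
                )
            )
            results["tests"].append(entry)
    lp = outdir / "local_results.json"
    io.write_json(results, lp)
    return [lp]


def stage_analyze_interplay(config: RunConfig, outdir: Path) -> list[Path]:
    feats = pd.read_csv(outdir / "features.csv").dropna(subset=["correct"])
    rows = []
    for n in config.interplay_n:
        for response in ("correct", "rt_ms"):
            rows.append(glmm.fit_local_global(feats, n, response=response))
    ip = outdir / "interplay.json"
    io.write_json({"seed": config.seed, "models": rows}, ip)
    flat = []
    for r in rows:
        for pred in ("global_std_25", "local_std_25", "last_soa_25"):
            flat.append(
                (r["N"], r["response"], pred, r[pred]["or"], r[pred]["ci_low"],
                 r[pred]["ci_high"])
            )
    pd.DataFrame(
        flat, columns=["N", "response", "predictor", "or", "ci_low", "ci_high"]
    ).to_csv(outdir / "interplay.csv", index=False)
    return [ip, outdir / "interplay.csv"]


def stage_analyze_rating(config: RunConfig, outdir: Path) -> list[Path]:
    feats = pd.read_csv(outdir / "features.csv").dropna(subset=["correct"])
    ratings = io.read_ratings_csv(outdir / "ratings.csv")
    excl = glmm.exclude_outlier_raters(ratings)
    kept = excl["kept"]
    out = glmm.rating_models(
        feats[feats["subject"].isin(kept)], ratings[ratings["subject"].isin(kept)]
    )
    results = {
        "seed": config.seed,
        "rater_exclusion": {k: excl[k] for k in ("kept", "excluded", "fences")},
        "slopes": excl["slopes"],
        "lrt_add_rating": dataclasses.asdict(out["lrt_add_rating"]),
        "rating_on_std_fit": _fit_summary(out["rating_on_std_fit"]),
    }
    rp = outdir / "rating_results.json"
    io.write_json(results, rp)
    log.info("rating analysis: excluded %s", excl["excluded"])
    return [rp]


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "features": stage_features,
    "analyze-global": stage_analyze_global,
    "analyze-local": stage_analyze_local,
    "analyze-interplay": stage_analyze_interplay,
    "analyze-rating": stage_analyze_rating,
}


def run_stage(name: str, config: RunConfig, outdir: str | Path) -> list[Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    return _STAGE_FUNCS[name](config, outdir)


def run_all(config: RunConfig, outdir: str | Path) -> dict:
    """Run every stage in order and write a manifest with checksums."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package_version": __version__,
        "config": config.to_dict(),
        "stages": {},
    }
    for name in STAGES:
        t0 = time.perf_counter()
        try:
            paths = run_stage(name, config, outdir)
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        manifest["stages"][name] = {
            "outputs": [p.name for p in paths],
            "checksums": {p.name: _sha256(p) for p in paths},
            "wall_clock_s": round(time.perf_counter() - t0, 3),
        }
    io.write_json(manifest, outdir / "manifest.json")
    report(outdir)
    return manifest


def report(outdir: str | Path) -> dict:
    """Assemble the per-stage artifacts into one summary (no recomputation)."""
    outdir = Path(outdir)
    summary: dict = {"sections": {}}
    trials_p = outdir / "trials.csv"
    if trials_p.exists():
        trials = pd.read_csv(trials_p)
        targets = trials.dropna(subset=["correct"])
        per_cond = (
            targets.groupby("condition_std_ms")
            .agg(acc=("correct", "mean"), rt_ms=("rt_ms", "mean"), n=("correct", "size"))
            .reset_index()
        )
        summary["sections"]["per_condition"] = per_cond.to_dict("records")
    for key, fname in [
        ("global", "global_results.json"),
        ("local", "local_results.json"),
        ("interplay", "interplay.json"),
        ("rating", "rating_results.json"),
    ]:
        p = outdir / fname
        summary["sections"][key] = io.read_json(p) if p.exists() else {"absent": True}
    io.write_json(summary, outdir / "report.json")
    lines = ["tempopred run summary", "====================="]
    if "per_condition" in summary["sections"]:
        lines.append("condition_std_ms  accuracy  mean RT (ms)      n")
        for r in summary["sections"]["per_condition"]:
            lines.append(
                f"{r['condition_std_ms']:>16g}  {r['acc']:8.3f}  {r['rt_ms']:12.1f}  {r['n']:5d}"
            )
    g = summary["sections"].get("global", {})
    if "accuracy" in g:
        lines.append(
            f"accuracy decline: {-g['accuracy']['ame_per_25ms_pp']:.2f} pp per 25 ms STD"
        )
        lines.append(f"RT slope: {g['rt']['slope_ms_per_25ms']:.2f} ms per 25 ms STD")
    for key in ("local", "interplay", "rating"):
        if summary["sections"].get(key, {}).get("absent"):
            lines.append(f"[{key} analysis absent]")
    (outdir / "report.txt").write_text("\n".join(lines) + "\n")
    return summary
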