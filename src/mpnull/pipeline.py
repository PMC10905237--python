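"""Orchestration: run the full analysis from a structured config.

Each stage reads the canonical population table, runs one analysis block and
writes delimited outputs plus a plain-text run log into the configured output
directory; the fully-resolved config (with its hash) is serialised alongside
for provenance.  The stages mirror the analysis: ``simulate`` (synthetic
cohort + trees), ``fit_null`` (per-population Bayesian null-model fits and
the deviation summary), ``compare`` (CMH / clustered rank-sum / t-tests /
consistency alpha), and ``phylo`` (phylogenetic mixed models).
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import replace as dc_replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import groupstats as gs
from . import nullmodel as nm
from . import phylo as ph
from . import synth
from .records import (
    PopulationRecord,
    assign_brood_size_cluster,
    pool_species,
    read_population_table,
    validate_record,
    write_population_table,
)

__all__ = [
    "load_run_config",
    "config_hash",
    "load_records",
    "cmd_simulate",
    "cmd_fit_null",
    "cmd_compare",
    "cmd_phylo",
]

DEFAULT_CONFIG = {
    "input": {"population_table": None, "delimiter": None, "column_map": None,
              "tree": None, "deviation_table": None},
    "filters": {"technique": None, "clade": None},
    "keep_invalid": False,
    "null_model": {"sire_rate_convention": "rate_plugin", "n_iter": 10000,
                   "n_burnin": 2000, "n_chains": 3, "seed": 1},
    "compare": {"group_by": "clade", "value": "prop_mp", "n_perm": 2000,
                "cmh_n_perm": 9999, "n_boot": 1000, "seed": 1},
    "phylo": {"n_iter": 4000, "n_burnin": 1000, "n_chains": 2, "seed": 1},
    "simulate": {"seed": 1, "siring": "monopolized"},
    "output_dir": "mpnull_out",
}


def _merge(base: dict, over: dict) -> dict:
    out = dict(base)
    for k, v in (over or {}).items():
        out[k] = _merge(base[k], v) if isinstance(v, dict) and isinstance(base.get(k), dict) else v
    return out


def load_run_config(path) -> dict:
    """Load a YAML run config, filling defaults for missing keys."""
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    return _merge(DEFAULT_CONFIG, user)


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        yaml.safe_dump(cfg, sort_keys=True).encode()
    ).hexdigest()[:12]


class _Run:
    """Output directory plus a stage-granularity run log."""

    def __init__(self, cfg: dict, stage: str):
        self.cfg = cfg
        self.dir = Path(cfg["output_dir"])
        self.dir.mkdir(parents=True, exist_ok=True)
        self.log_path = self.dir / f"{stage}.log"
        self.lines: list[str] = []
        with open(self.dir / f"{stage}_config.yaml", "w") as fh:
            yaml.safe_dump({"config_hash": config_hash(cfg), **cfg}, fh, sort_keys=True)

    def log(self, msg: str) -> None:
        self.lines.append(msg)

    def close(self) -> None:
        self.log_path.write_text("\n".join(self.lines) + "\n")


def load_records(cfg: dict, run: _Run | None = None) -> list[PopulationRecord]:
    """Read, filter and validate the population table per the config."""
    inp = cfg["input"]
    if not inp.get("population_table"):
        raise ValueError("config gives no input population_table")
    records = read_population_table(
        inp["population_table"], delimiter=inp.get("delimiter"),
        column_map=inp.get("column_map"),
    )
    note = lambda m: run.log(m) if run else None
    note(f"read {len(records)} records from {inp['population_table']}")
    for key in ("technique", "clade"):
        want = cfg["filters"].get(key)
        if want:
            records = [r for r in records if getattr(r, key) == want]
            note(f"filter {key}={want}: {len(records)} records remain")
    if not records:
        raise ValueError("no records remain after filtering")
    valid, violations = [], []
    for r in records:
        v = validate_record(r)
        if v:
            violations.extend((r.population_id, x.invariant, x.message) for x in v)
        if not v or cfg.get("keep_invalid"):
            valid.append(r)
    if run and violations:
        pd.DataFrame(violations, columns=["population_id", "invariant", "detail"]).to_csv(
            run.dir / "violations.csv", index=False
        )
    note(f"{len(valid)} records kept ({len(violations)} invariant violations)")
    return valid


def cmd_simulate(cfg: dict) -> dict:
    """Generate the synthetic cohort, trees and canonical tables."""
    run = _Run(cfg, "simulate")
    sim = cfg["simulate"]
    scfg = synth.SyntheticConfig.study_default(
        seed=int(sim["seed"]), siring=sim.get("siring", "monopolized")
    )
    scale = float(sim.get("scale", 1.0))
    if scale != 1.0:
        scfg = synth.SyntheticConfig(
            regimes=tuple(
                dc_replace(
                    r,
                    n_populations=max(2, int(round(r.n_populations * scale))),
                    n_species=max(2, int(round((r.n_species or r.n_populations) * scale))),
                )
                for r in scfg.regimes
            ),
            seed=scfg.seed, siring=scfg.siring, null_theta=scfg.null_theta,
        )
    records, _broods = synth.gen_cohort(scfg)
    table_path = run.dir / "populations.csv"
    write_population_table(records, table_path)
    run.log(f"wrote {len(records)} populations to {table_path}")
    # one Yule tree per clade, tips named after the cohort's species, grafted
    clades = sorted({r.clade for r in records})
    subtrees = []
    ss = np.random.SeedSequence(int(sim["seed"]) + 1).generate_state(len(clades))
    for cseed, clade in zip(ss, clades):
        species = sorted({r.species_name for r in records if r.clade == clade})
        tree = synth.gen_yule_tree(len(species), 1.0, seed=int(cseed) % 2**31)
        for leaf, name in zip(tree.dendropy_tree.leaf_node_iter(), species):
            leaf.taxon.label = name
        tree = ph.parse_newick(tree.newick())
        subtrees.append(tree)
        run.log(f"{clade}: {len(species)} species tree, depth {tree.depth:.3f}")
    if len(subtrees) == 2:
        div = 2.0 * max(t.depth for t in subtrees)
        combined = ph.graft_trees(subtrees[0], subtrees[1], div)
    else:
        combined = subtrees[0]
    tree_path = run.dir / "combined_tree.nwk"
    tree_path.write_text(combined.newick() + "\n")
    run.log(f"wrote grafted tree ({combined.n_tips} tips) to {tree_path}")
    run.close()
    return {"population_table": str(table_path), "tree": str(tree_path),
            "n_records": len(records)}


def _null_cfg(cfg: dict) -> nm.NullModelConfig:
    c = cfg["null_model"]
    return nm.NullModelConfig(
        sire_rate_convention=c.get("sire_rate_convention", "rate_plugin"),
        n_iter=int(c.get("n_iter", 10000)), n_burnin=int(c.get("n_burnin", 2000)),
        n_chains=int(c.get("n_chains", 3)), seed=int(c.get("seed", 1)),
    )


def cmd_fit_null(cfg: dict) -> dict:
    """Fit the null model per population; write fits, summary and pB curve."""
    run = _Run(cfg, "fit_null")
    records = load_records(cfg, run)
    base = _null_cfg(cfg)
    seeds = np.random.SeedSequence(base.seed).generate_state(len(records))
    fits = []
    for s, rec in zip(seeds, records):
        fit = nm.fit_null_model(rec, nm.NullModelConfig(
            sire_rate_convention=base.sire_rate_convention, n_iter=base.n_iter,
            n_burnin=base.n_burnin, n_chains=base.n_chains, seed=int(s) % 2**31,
        ))
        if fit.warnings:
            run.log(f"{rec.population_id}: " + "; ".join(fit.warnings))
        fits.append(fit)
    table, agg = nm.deviation_summary(fits, records)
    table.to_csv(run.dir / "deviation_summary.csv", index=False)
    with open(run.dir / "deviation_aggregates.json", "w") as fh:
        json.dump(agg, fh, indent=2)
    # null-prediction curve from the pooled posterior of θ
    pooled_theta = np.concatenate([
        f.theta_samples for f in fits if not f.degenerate
    ]) if any(not f.degenerate for f in fits) else np.array([1.0])
    sub = pooled_theta[:: max(1, len(pooled_theta) // 4000)]
    nm.pb_curve(sub).to_csv(run.dir / "pb_curve.csv", index=False)
    run.log(f"fitted {len(fits)} populations; mean deviation {agg['mean_deviation']:.4f}")
    run.close()
    return {"fits": fits, "table": table, "aggregates": agg, "output_dir": str(run.dir)}


_GROUPERS = {
    "clade": (lambda r: r.clade, None),
    "technique": (lambda r: r.technique, None),
    "mating_system": (
        lambda r: r.mating_system if r.mating_system in ("monogamous", "other") else None,
        ("monogamous", "other"),
    ),
}


def cmd_compare(cfg: dict) -> dict:
    """Group comparisons: zero-MP CMH, clustered rank-sum, t-tests, alpha."""
    run = _Run(cfg, "compare")
    records = load_records(cfg, run)
    comp = cfg["compare"]
    group_by = comp.get("group_by", "clade")
    if group_by not in _GROUPERS:
        raise ValueError(f"unknown grouping {group_by!r}")
    grouper, order = _GROUPERS[group_by]
    labelled = [(grouper(r), r) for r in records]
    labelled = [(g, r) for g, r in labelled if g is not None]
    levels = order or tuple(sorted({g for g, _ in labelled}))
    if len(levels) < 2:
        raise ValueError(f"grouping {group_by!r} has fewer than 2 levels")
    seed = int(comp.get("seed", 1))
    rows = []

    # CMH on zero multiple paternity across brood-size clusters
    strat = gs.build_stratified_table(
        [r for _, r in labelled], grouper, lambda r: r.prop_mp == 0.0, groups=levels
    )
    cmh = gs.cmh_permutation_test(strat, n_perm=int(comp.get("cmh_n_perm", 9999)), seed=seed)
    rows.append(("cmh_zero_mp", cmh.cor, cmh.p_value, strat.total, seed,
                 f"groups={levels}; clor={cmh.clor:.4f}"))

    # clustered Wilcoxon on the chosen value column (default observed p)
    value_cols = [comp.get("value", "prop_mp")]
    dev_path = cfg["input"].get("deviation_table")
    dev_by_id = {}
    if dev_path:
        dev = pd.read_csv(dev_path)
        dev_by_id = dict(zip(dev["population_id"], dev["deviation"]))
        value_cols.append("deviation")
    for col in value_cols:
        vals, grp, clus = [], [], []
        for g, r in labelled:
            v = dev_by_id.get(r.population_id) if col == "deviation" else getattr(r, col)
            if v is None or (isinstance(v, float) and math.isnan(v)):
                continue
            vals.append(v)
            grp.append(g)
            clus.append(assign_brood_size_cluster(r.mean_brood_size))
        res = gs.clustered_rank_sum_test(
            vals, grp, clus, n_perm=int(comp.get("n_perm", 2000)), seed=seed
        )
        means = {
            lev: float(np.mean([v for v, g in zip(vals, grp) if g == lev]))
            for lev in levels
        }
        rows.append((f"clustered_ranksum_{col}", res.w, res.p_value, len(vals), seed,
                     "; ".join(f"mean[{k}]={v:.4f}" for k, v in means.items())))

    # Welch t-tests on the reported summaries (first two levels)
    a = [r for g, r in labelled if g == levels[0]]
    b = [r for g, r in labelled if g == levels[1]]
    for col in ("mean_n_sires", "mean_brood_size", "n_broods"):
        t = gs.welch_t([getattr(r, col) for r in a], [getattr(r, col) for r in b])
        rows.append((f"welch_t_{col}", t.t, t.p_value, len(a) + len(b), seed,
                     f"mean[{levels[0]}]={t.mean_a:.4f}; mean[{levels[1]}]={t.mean_b:.4f}"))

    # within-species consistency of repeated population measurements
    for col in ("prop_mp", "mean_brood_size"):
        matrix = _species_population_matrix(records, col)
        if matrix is not None:
            alpha = gs.alpha_bootstrap_ci(
                matrix, n_boot=int(comp.get("n_boot", 1000)), seed=seed
            )
            rows.append((f"krippendorff_alpha_{col}", alpha.alpha, float("nan"),
                         matrix.shape[0], seed,
                         f"ci=({alpha.ci[0]:.3f},{alpha.ci[1]:.3f})"))

    report = pd.DataFrame(rows, columns=["test", "statistic", "p_value", "n", "seed", "settings"])
    report.to_csv(run.dir / "tests_report.csv", index=False)
    run.log(f"wrote {len(report)} test rows")
    run.close()
    return {"report": report, "stratified_table": strat, "output_dir": str(run.dir)}


def _species_population_matrix(records, col: str):
    """Units × observers matrix (species × repeat populations) for alpha."""
    groups: dict[str, list[float]] = {}
    for r in records:
        groups.setdefault(r.species_name, []).append(getattr(r, col))
    multi = [v for v in groups.values() if len(v) >= 2]
    if len(multi) < 2:
        return None
    width = max(len(v) for v in multi)
    return np.array([v + [np.nan] * (width - len(v)) for v in multi])


def cmd_phylo(cfg: dict) -> dict:
    """Species aggregation, correlation matrix, and the mixed-model suite."""
    run = _Run(cfg, "phylo")
    records = load_records(cfg, run)
    tree_path = cfg["input"].get("tree")
    if not tree_path:
        raise ValueError("config gives no input tree")
    tree = ph.parse_newick(Path(tree_path).read_text())
    species_records = pool_species(records, strategy="unweighted")
    by_species = {r.species_name: r for r in species_records}
    tips = set(tree.tip_labels)
    missing = sorted(set(by_species) - tips)
    if missing:
        run.log(f"{len(missing)} species not in tree; dropped: {missing[:5]} ...")
    keep = sorted(set(by_species) & tips)
    extra = sorted(tips - set(by_species))
    if extra:
        run.log(f"{len(extra)} tree tips without data are retained in C and subset out")
    if len(keep) < 3:
        raise ValueError("fewer than 3 species shared between table and tree")
    C = ph.phylo_correlation(tree).loc[keep, keep]
    # renormalise the subset so the diagonal stays 1 (depth rescaling)
    C = C / np.max(np.diag(C.values))

    pcfg = cfg["phylo"]
    mk = lambda s: ph.PMMConfig(
        n_iter=int(pcfg.get("n_iter", 4000)), n_burnin=int(pcfg.get("n_burnin", 1000)),
        n_chains=int(pcfg.get("n_chains", 2)), seed=int(pcfg.get("seed", 1)) + s,
    )
    dev_path = cfg["input"].get("deviation_table")
    rows = []
    fits = {}

    y_bin = pd.Series({s: int(by_species[s].prop_mp > 0.0) for s in keep})
    x_clade = pd.Series({s: float(by_species[s].clade == "mammal") for s in keep})
    two_clades = 0.0 < x_clade.mean() < 1.0
    fit_b = ph.fit_pmm_binary(y_bin, x_clade if two_clades else None, C, mk(1))
    fits["mp_binary"] = fit_b
    h, ci = ph.phylo_heritability(fit_b)
    rows.append(("pmm_binary_mp_h", h, ci[0], ci[1]))
    if two_clades:
        rows.append(("pmm_binary_mp_lor_mammal", fit_b.summaries["lor_mean"],
                     *fit_b.summaries["lor_ci"]))

    y_p = pd.Series({s: by_species[s].prop_mp for s in keep})
    fit_p = ph.fit_pmm_gaussian(y_p, None, C, mk(2))
    fits["p_gaussian"] = fit_p
    h, ci = ph.phylo_heritability(fit_p)
    rows.append(("pmm_gaussian_p_h", h, ci[0], ci[1]))

    if dev_path:
        dev = pd.read_csv(dev_path)
        dev_sp = dev.groupby("species_name")["deviation"].mean()
        y_dev = dev_sp.reindex(keep).dropna()
        if len(y_dev) >= 3:
            Cd = C.loc[y_dev.index, y_dev.index]
            fit_d = ph.fit_pmm_gaussian(
                y_dev, x_clade.reindex(y_dev.index) if two_clades else None, Cd, mk(3)
            )
            fits["deviation_gaussian"] = fit_d
            h, ci = ph.phylo_heritability(fit_d)
            rows.append(("pmm_gaussian_deviation_h", h, ci[0], ci[1]))
            if two_clades:
                rows.append(("pmm_gaussian_deviation_delta_mammal",
                             fit_d.summaries["delta_mean"], *fit_d.summaries["delta_ci"]))

    masses = {s: by_species[s].body_mass for s in keep if by_species[s].body_mass}
    if len(masses) >= 3:
        y_mass = pd.Series({s: math.log10(m) for s, m in masses.items()})
        Cm = C.loc[y_mass.index, y_mass.index]
        fit_m = ph.fit_pmm_gaussian(y_mass, None, Cm, mk(4))
        fits["log10_mass_gaussian"] = fit_m
        h, ci = ph.phylo_heritability(fit_m)
        rows.append(("pmm_gaussian_log10mass_h", h, ci[0], ci[1]))

    report = pd.DataFrame(rows, columns=["quantity", "estimate", "ci_lo", "ci_hi"])
    report.to_csv(run.dir / "pmm_report.csv", index=False)
    run.log(f"fitted {len(fits)} mixed models on {len(keep)} species")
    run.close()
    return {"report": report, "fits": fits, "n_species": len(keep),
            "output_dir": str(run.dir)}
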