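"""Pipeline orchestration, diagnostics, and the replication look-up.

``run_pipeline`` ties the stages together: simulate cohort and methylome,
deconvolve cell composition, run the three exposure-specification EWAS
with q-values and inflation diagnostics, Monte-Carlo contrasts for top
hits, DMR calling per exposure term, co-methylation network modules with
eigengene-trait tests, enrichment of module gene lists, and the external
replication look-up. One master seed deterministically derives per-stage
seeds by stable stage-name hashing.
"""

from __future__ import annotations

import json
import logging
import time
import zlib
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig
from .contrast import contrast_table
from .core import deconvolve_cohort, pairwise_ace_odds_ratios
from .dmr import call_dmrs, dmr_table
from .enrichment import biased_set_test
from .ewas import EwasResult, build_design, categorical_high_vs_mid_contrast, fit_moderated
from .io import dmr_calls_to_bed, write_cohort, write_matrix, write_table
from .network import detect_modules, me_trait_tests, module_eigengenes, pick_soft_power, tom_matrix
from .synthetic import simulate_cohort, simulate_methylome

logger = logging.getLogger(__name__)


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31 from the master seed."""
    return (int(master_seed) * 1_000_003 + zlib.crc32(stage.encode())) % (2**31 - 1)


def qq_table(pvals: np.ndarray) -> pd.DataFrame:
    """Expected vs observed -log10 p quantiles plus the inflation factor."""
    from .ewas import genomic_lambda

    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    p = np.clip(p, 1e-300, 1.0)
    obs = np.sort(p)
    m = p.size
    expected = np.arange(1, m + 1) / (m + 1)
    out = pd.DataFrame(
        {
            "expected_log10": -np.log10(expected),
            "observed_log10": -np.log10(obs),
        }
    )
    out.attrs["lambda"] = genomic_lambda(p)
    return out


def replication_lookup(
    ewas_tables: dict[str, pd.DataFrame], external: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Count nominally significant look-up CpGs per model/term.

    ``external`` must carry a ``cpg_id`` column; CpGs absent from a model's
    results are reported in the ``n_missing`` column.
    """
    if "cpg_id" not in external.columns:
        raise ValueError("external table needs a cpg_id column")
    wanted = set(external["cpg_id"])
    rows = []
    for model, table in ewas_tables.items():
        for term, grp in table.groupby("term", sort=False):
            present = grp[grp["cpg_id"].isin(wanted)]
            rows.append(
                dict(
                    model=model,
                    term=term,
                    n_lookup=len(wanted),
                    n_found=len(present),
                    n_missing=len(wanted) - len(present),
                    n_nominal=int((present["p"] < alpha).sum()),
                )
            )
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig, gene_sets: dict | None = None,
                 external_cpgs: pd.DataFrame | None = None) -> Path:
    """Execute the full analysis; returns the run directory.

    Rerunning with the same configuration reproduces every output: all
    randomness flows from the master seed through per-stage seeds.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "master_seed": config.master_seed,
        "parameters": asdict(config),
        "stages": {},
    }

    def _stage(name):
        t0 = time.time()
        logger.info("stage %s ...", name)
        return t0

    def _done(name, t0):
        manifest["stages"][name] = round(time.time() - t0, 3)
        logger.info("stage %s done in %.1fs", name, manifest["stages"][name])

    try:
        t0 = _stage("simulate")
        cohort_cfg = config.cohort
        cohort_cfg.seed = stage_seed(config.master_seed, "cohort")
        cohort = simulate_cohort(cohort_cfg)
        meth_cfg = config.methylome
        meth_cfg.seed = stage_seed(config.master_seed, "methylome")
        matrix, reference, truth = simulate_methylome(cohort, meth_cfg)
        write_cohort(cohort, out / "cohort.tsv", params={"seed": cohort_cfg.seed})
        write_matrix(matrix, out / "betas.tsv", out / "annotation.bed.tsv",
                     params={"seed": meth_cfg.seed})
        write_table(reference, out / "cell_reference.tsv")
        _done("simulate", t0)

        t0 = _stage("deconvolve")
        cell_props = deconvolve_cohort(matrix, reference)
        write_table(cell_props, out / "cell_proportions.tsv")
        _done("deconvolve", t0)

        t0 = _stage("descriptives")
        ors = pairwise_ace_odds_ratios(cohort)
        write_table(ors, out / "ace_pairwise_or.tsv", index=False)
        _done("descriptives", t0)

        ewas_results: dict[str, EwasResult] = {}
        ewas_tables: dict[str, pd.DataFrame] = {}
        for mode in config.specs:
            t0 = _stage(f"ewas_{mode}")
            design = build_design(cohort, mode, cell_proportions=cell_props)
            res = fit_moderated(matrix, design)
            table = res.table
            if mode == "total_categorical":
                extra = categorical_high_vs_mid_contrast(res)
                table = pd.concat([table, extra], ignore_index=True)
            ewas_results[mode] = res
            ewas_tables[mode] = table
            write_table(table, out / f"ewas_{mode}.tsv", index=False,
                        params={"mode": mode, "lambda": res.lambdas.to_dict(),
                                "pi0": float(res.pi0.iloc[0]), "max_vif": float(design.vif.max())})
            qq = qq_table(res.table["p"].to_numpy())
            write_table(qq, out / f"qq_{mode}.tsv", index=False,
                        params={"lambda": qq.attrs["lambda"]})
            _done(f"ewas_{mode}", t0)

        t0 = _stage("contrasts")
        for mode, res in ewas_results.items():
            top = res.table.nsmallest(config.n_top_contrasts, "p")
            ct = contrast_table(
                res, list(dict.fromkeys(top["cpg_id"])), n_draws=config.n_draws,
                seed=stage_seed(config.master_seed, f"contrast_{mode}"),
            )
            write_table(ct, out / f"contrasts_{mode}.tsv", index=False)
        _done("contrasts", t0)

        t0 = _stage("dmr")
        ann = matrix.cpg_annotation
        all_calls = []
        for mode, res in ewas_results.items():
            for term, grp in res.table.groupby("term", sort=False):
                grp = grp.reset_index(drop=True)
                calls, _ = call_dmrs(
                    grp["p"].to_numpy(), grp["pos"].to_numpy(), grp["chrom"].to_numpy(),
                    max_gap=config.dmr_max_gap, seed_p=config.dmr_seed_p,
                    min_cpgs=config.dmr_min_cpgs,
                    effect_signs=np.sign(grp["coef"].to_numpy()),
                )
                tab = dmr_table(calls)
                tab.insert(0, "term", term)
                tab.insert(0, "model", mode)
                all_calls.append(tab)
        all_calls = [t for t in all_calls if len(t)]
        dmrs = pd.concat(all_calls, ignore_index=True) if all_calls else pd.DataFrame()
        write_table(dmrs, out / "dmrs.tsv", index=False,
                    params={"max_gap": config.dmr_max_gap, "seed_p": config.dmr_seed_p,
                            "min_cpgs": config.dmr_min_cpgs})
        if len(dmrs):
            write_table(dmr_calls_to_bed(dmrs), out / "dmrs.bed.tsv", index=False)
        _done("dmr", t0)

        t0 = _stage("network")
        m_vals = matrix.to_m().values
        # desk-scale single-block computation; subsample CpGs if very large
        max_network = 4000
        if m_vals.shape[0] > max_network:
            rng = np.random.default_rng(stage_seed(config.master_seed, "network_subsample"))
            net_idx = np.sort(rng.choice(m_vals.shape[0], size=max_network, replace=False))
        else:
            net_idx = np.arange(m_vals.shape[0])
        net_m = m_vals[net_idx]
        power, fits = pick_soft_power(net_m)
        tom = tom_matrix(net_m, power)
        labels = detect_modules(tom, net_m, min_size=config.network_min_module_size,
                                merge_threshold=config.network_merge_threshold)
        modules = module_eigengenes(
            net_m, labels, matrix.sample_ids, power=power,
            chroms=ann["chrom"].to_numpy()[net_idx],
        )
        assign = pd.DataFrame({"cpg_id": ann.index.to_numpy()[net_idx], "module": labels})
        write_table(assign, out / "modules.tsv", index=False,
                    params={"power": power, "min_size": config.network_min_module_size})
        if modules.eigengenes is not None and len(modules.eigengenes.columns):
            write_table(modules.eigengenes, out / "eigengenes.tsv")
            rep = pd.DataFrame({
                "variance_explained_pct": modules.variance_explained,
                "median_abs_kme": modules.median_abs_kme,
            })
            write_table(rep, out / "module_representativeness.tsv")
            for mode in config.specs:
                mt = me_trait_tests(modules, cohort, mode, cell_proportions=cell_props)
                write_table(mt, out / f"me_trait_{mode}.tsv", index=False,
                            params={"fdr_method": mt.attrs.get("fdr_method", "")})
        _done("network", t0)

        t0 = _stage("enrich")
        if gene_sets and modules.eigengenes is not None:
            cpg_gene = dict(zip(ann.index, ann["gene"]))
            universe = list(ann.index.to_numpy()[net_idx])
            enr_all = []
            for mod in modules.module_names():
                sel = list(np.asarray(universe)[labels == mod])
                tab = biased_set_test(sel, universe, cpg_gene, gene_sets)
                tab.insert(0, "module", mod)
                enr_all.append(tab)
            if enr_all:
                write_table(pd.concat(enr_all, ignore_index=True), out / "enrichment.tsv", index=False)
        _done("enrich", t0)

        t0 = _stage("lookup")
        if external_cpgs is not None:
            look = replication_lookup(ewas_tables, external_cpgs)
            write_table(look, out / "replication_lookup.tsv", index=False)
        _done("lookup", t0)
    except Exception as exc:  # partial outputs retained for debugging
        manifest["failed_stage"] = str(exc)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        raise RuntimeError(f"pipeline stage failed: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return out
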