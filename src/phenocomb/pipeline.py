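"""Stage functions behind the command-line interface.

Stages communicate through TSV artifacts in the configured output
directory, so each stage is idempotent, resumable and independently
inspectable:

    simulate   -> panel.{dosages,snps}.tsv, panel.{bed,bim,fam},
                  components.tsv, external_<trait>.sumstats.tsv
    phenotypes -> manifest.tsv, phenotypes/<name>.tsv
    h2         -> h2_estimates.tsv, h2_blocks.tsv
    rg         -> rg_<trait>.tsv, rg_blocks_<trait>.tsv, ld_scores.tsv
    compare    -> trend_h2.tsv, attribution_h2.tsv and the rg analogues
    report     -> report.json, report.tsv
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Dict, List

import numpy as np
import pandas as pd

from . import compare as cmp
from . import h2pcgc, io, ldscore, phenogrid, simgen
from .config import RunConfig

__all__ = [
    "DependencyError",
    "stage_simulate",
    "stage_phenotypes",
    "stage_h2",
    "stage_rg",
    "stage_compare",
    "stage_report",
    "run_all",
]

logger = logging.getLogger(__name__)

STAGES = ("simulate", "phenotypes", "h2", "rg", "compare", "report")


class DependencyError(RuntimeError):
    """An upstream stage's outputs are missing."""


def _meta(cfg: RunConfig, stage: str) -> Dict[str, str]:
    return {
        "config_hash": cfg.config_hash,
        "seed": str(cfg.simulation.seed),
        "stage": stage,
    }


def _require(outdir: Path, filename: str, produced_by: str) -> Path:
    path = outdir / filename
    if not path.exists():
        raise DependencyError(
            f"missing {path}; run the '{produced_by}' stage first"
        )
    return path


def _pheno_filename(name: str) -> str:
    return name.replace(" + ", "_") + ".tsv"


def _definitions(cfg: RunConfig) -> List[phenogrid.PhenotypeDefinition]:
    return phenogrid.enumerate_phenotypes(cfg.components)


# ------------------------------------------------------------------ stages

def stage_simulate(cfg: RunConfig, outdir: Path) -> None:
    s = cfg.simulation
    panel = simgen.simulate_genotypes(
        s.n, s.m, s.maf_bounds, s.n_chrom, s.seed,
        bp_spacing=s.bp_spacing, ld_block_size=s.ld_block_size,
        ld_copy_prob=s.ld_copy_prob,
    )
    arch = s.architecture.build()
    table = simgen.simulate_components(panel, arch, s.seed, missing_rate=s.missing_rate)
    meta = _meta(cfg, "simulate")
    io.write_panel_tsv(panel, outdir / "panel", meta)
    io.write_plink(panel, outdir / "panel")
    io.write_component_table(table, outdir / "components.tsv", meta)
    for trait in s.external_traits:
        ss = simgen.simulate_external_sumstats(panel, arch, trait, s.n_external, s.seed)
        io.write_tsv(outdir / f"external_{trait}.sumstats.tsv", ss.to_frame(), meta)
    logger.info("simulate: n=%d m=%d, %d external trait(s)", s.n, s.m,
                len(s.external_traits))


def stage_phenotypes(cfg: RunConfig, outdir: Path) -> None:
    _require(outdir, "components.tsv", "simulate")
    table = io.read_component_table(outdir / "components.tsv")
    meta = _meta(cfg, "phenotypes")
    rows = []
    for defn in _definitions(cfg):
        asg = phenogrid.assign_case_control(table, defn)
        io.write_phenotype_file(
            asg, table.individual_ids, outdir / "phenotypes" / _pheno_filename(defn.name),
            meta,
        )
        rows.append(
            {
                "phenotype": defn.name,
                "components": ",".join(defn.components) or "-",
                "enrichment": defn.enrichment,
                "n_cases": asg.n_cases,
                "n_controls": asg.n_controls,
                "prevalence_pre_exclusion": asg.sample_prevalence_pre_exclusion,
                "degenerate": int(asg.degenerate),
            }
        )
    io.write_tsv(outdir / "manifest.tsv", pd.DataFrame(rows), meta)
    logger.info("phenotypes: %d definitions", len(rows))


def stage_h2(cfg: RunConfig, outdir: Path) -> None:
    _require(outdir, "manifest.tsv", "phenotypes")
    table = io.read_component_table(outdir / "components.tsv")
    panel = io.read_panel_tsv(outdir / "panel")
    e = cfg.estimation
    panel_h2, n_removed = h2pcgc.exclude_region(
        panel, e.mhc_chrom, e.mhc_start_bp, e.mhc_end_bp
    )
    logger.info("h2: removed %d SNPs in the excluded region", n_removed)
    grm = h2pcgc.compute_grm(panel_h2)
    blocks = cmp.make_blocks(panel.n, e.n_blocks, e.jackknife_seed)

    meta = _meta(cfg, "h2")
    rows, reps = [], {}
    for defn in _definitions(cfg):
        asg = phenogrid.assign_case_control(table, defn)
        try:
            est = h2pcgc.pcgc_h2(asg, grm, blocks=blocks)
        except h2pcgc.EstimationError as exc:
            logger.warning("h2: skipping %s (%s)", defn.name, exc)
            est = None
        rows.append(
            {
                "phenotype": defn.name,
                "enrichment": defn.enrichment,
                "n_cases": asg.n_cases,
                "n_controls": asg.n_controls,
                "K": asg.K,
                "P": est.P if est else float("nan"),
                "h2_obs": est.h2_observed if est else float("nan"),
                "h2_liab": est.h2_liability if est else float("nan"),
                "se_liab": est.se_liability if est else float("nan"),
                "p": est.p_value if est else float("nan"),
            }
        )
        reps[defn.name] = (
            est.block_replicates if est else np.full(e.n_blocks, np.nan)
        )
    io.write_tsv(outdir / "h2_estimates.tsv", pd.DataFrame(rows), meta)
    blocks_df = pd.DataFrame(reps).T
    blocks_df.columns = [f"b{i}" for i in range(blocks_df.shape[1])]
    blocks_df.insert(0, "phenotype", blocks_df.index)
    io.write_tsv(outdir / "h2_blocks.tsv", blocks_df.reset_index(drop=True), meta)


def stage_rg(cfg: RunConfig, outdir: Path) -> None:
    _require(outdir, "manifest.tsv", "phenotypes")
    table = io.read_component_table(outdir / "components.tsv")
    panel = io.read_panel_tsv(outdir / "panel")
    e = cfg.estimation
    panel_rg, _ = h2pcgc.exclude_region(
        panel, e.mhc_chrom, e.mhc_start_bp, e.mhc_end_bp
    )
    ld = ldscore.compute_ld_scores(panel_rg, e.ld_window_bp)
    meta = _meta(cfg, "rg")
    io.write_tsv(outdir / "ld_scores.tsv", ld.to_frame(), meta)
    snp_blocks = cmp.make_blocks(panel_rg.m, min(e.n_blocks, panel_rg.m), e.jackknife_seed + 1)

    # per-phenotype GWAS summaries are shared across external traits
    gwas_cache: Dict[str, ldscore.AssocSummary] = {}
    for defn in _definitions(cfg):
        asg = phenogrid.assign_case_control(table, defn)
        valid = (asg.status == phenogrid.CASE) | (asg.status == phenogrid.CONTROL)
        idx = np.flatnonzero(valid)
        if asg.degenerate:
            logger.warning("rg: skipping degenerate %s", defn.name)
            continue
        y = (asg.status[idx] == phenogrid.CASE).astype(np.float64)
        sub = simgen.GenotypePanel(
            dosages=panel_rg.dosages[idx],
            snp_ids=panel_rg.snp_ids, chrom=panel_rg.chrom, bp=panel_rg.bp,
            a1=panel_rg.a1, a2=panel_rg.a2, freq=panel_rg.freq,
            individual_ids=panel_rg.individual_ids[idx],
        )
        gwas_cache[defn.name] = ldscore.run_gwas(sub, h2pcgc.residualize(y))

    for trait in cfg.simulation.external_traits:
        path = _require(outdir, f"external_{trait}.sumstats.tsv", "simulate")
        df, _ = io.read_tsv(path)
        ext = ldscore.AssocSummary(
            snp_ids=df["SNP"].to_numpy(dtype=str),
            a1=df["A1"].to_numpy(dtype=str),
            a2=df["A2"].to_numpy(dtype=str),
            z=df["Z"].to_numpy(dtype=np.float64),
            n_eff=df["N"].to_numpy(dtype=np.int64),
        )
        rows, reps = [], {}
        for defn in _definitions(cfg):
            ss = gwas_cache.get(defn.name)
            if ss is None:
                continue
            try:
                est = ldscore.ldsc_rg(ss, ext, ld, panel_rg.m, blocks=snp_blocks)
            except ldscore.LdscError as exc:
                logger.warning("rg: %s vs %s failed (%s)", defn.name, trait, exc)
                est = None
            rows.append(
                {
                    "phenotype": defn.name,
                    "external_trait": trait,
                    "enrichment": defn.enrichment,
                    "rg": est.rg if est else float("nan"),
                    "se": est.se if est else float("nan"),
                    "p": est.p_value if est else float("nan"),
                    "h2_1": est.h2_1 if est else float("nan"),
                    "h2_2": est.h2_2 if est else float("nan"),
                    "intercept_1": est.intercepts[0] if est else float("nan"),
                    "intercept_2": est.intercepts[1] if est else float("nan"),
                    "intercept_biv": est.intercepts[2] if est else float("nan"),
                }
            )
            reps[defn.name] = (
                est.block_replicates if est else np.full(len(snp_blocks), np.nan)
            )
        io.write_tsv(outdir / f"rg_{trait}.tsv", pd.DataFrame(rows), meta)
        blocks_df = pd.DataFrame(reps).T
        blocks_df.columns = [f"b{i}" for i in range(blocks_df.shape[1])]
        blocks_df.insert(0, "phenotype", blocks_df.index)
        io.write_tsv(outdir / f"rg_blocks_{trait}.tsv", blocks_df.reset_index(drop=True), meta)


def _block_estimates(est_df: pd.DataFrame, blocks_df: pd.DataFrame,
                     value_col: str) -> List[cmp.BlockEstimate]:
    reps = blocks_df.set_index("phenotype")
    out = []
    for _, row in est_df.iterrows():
        out.append(
            cmp.BlockEstimate(
                name=row["phenotype"],
                value=float(row[value_col]),
                replicates=reps.loc[row["phenotype"]].to_numpy(dtype=np.float64),
                enrichment=int(row["enrichment"]),
            )
        )
    return out


def _summaries_frame(summaries) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "group": s.group,
                "mean_delta": s.mean_delta,
                "se": s.se,
                "p": s.p,
                "n_members": s.n_members,
            }
            for s in summaries
        ]
    )


def stage_compare(cfg: RunConfig, outdir: Path) -> None:
    _require(outdir, "h2_estimates.tsv", "h2")
    meta = _meta(cfg, "compare")
    pairs = phenogrid.component_pairs(_definitions(cfg))
    reference = phenogrid.PhenotypeDefinition(components=()).name

    est_df, _ = io.read_tsv(outdir / "h2_estimates.tsv")
    blocks_df, _ = io.read_tsv(_require(outdir, "h2_blocks.tsv", "h2"))
    ests = _block_estimates(est_df, blocks_df, "h2_liab")
    trend = cmp.enrichment_trend(ests, reference)
    attrib = cmp.component_attribution(ests, pairs)
    io.write_tsv(outdir / "trend_h2.tsv", _summaries_frame(trend), meta)
    io.write_tsv(
        outdir / "attribution_h2.tsv",
        _summaries_frame(attrib["cells"] + attrib["overall"]),
        meta,
    )

    for trait in cfg.simulation.external_traits:
        est_df, _ = io.read_tsv(_require(outdir, f"rg_{trait}.tsv", "rg"))
        blocks_df, _ = io.read_tsv(_require(outdir, f"rg_blocks_{trait}.tsv", "rg"))
        ests = _block_estimates(est_df, blocks_df, "rg")
        trend = cmp.enrichment_trend(ests, reference)
        attrib = cmp.component_attribution(ests, pairs)
        io.write_tsv(outdir / f"trend_rg_{trait}.tsv", _summaries_frame(trend), meta)
        io.write_tsv(
            outdir / f"attribution_rg_{trait}.tsv",
            _summaries_frame(attrib["cells"] + attrib["overall"]),
            meta,
        )


def stage_report(cfg: RunConfig, outdir: Path) -> None:
    _require(outdir, "trend_h2.tsv", "compare")
    meta = _meta(cfg, "report")
    bundle: Dict[str, object] = {"config_hash": cfg.config_hash,
                                 "seed": cfg.simulation.seed}
    tables = ["manifest", "h2_estimates", "trend_h2", "attribution_h2"]
    for trait in cfg.simulation.external_traits:
        tables += [f"rg_{trait}", f"trend_rg_{trait}", f"attribution_rg_{trait}"]
    frames = []
    for name in tables:
        df, _ = io.read_tsv(_require(outdir, f"{name}.tsv", "earlier"))
        bundle[name] = json.loads(df.to_json(orient="records"))
        tagged = df.copy()
        tagged.insert(0, "table", name)
        frames.append(tagged)
    (outdir / "report.json").write_text(
        json.dumps(bundle, indent=2, sort_keys=True, allow_nan=True) + "\n"
    )
    io.write_tsv(
        outdir / "report.tsv",
        pd.concat(frames, ignore_index=True, sort=False),
        meta,
    )


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "phenotypes": stage_phenotypes,
    "h2": stage_h2,
    "rg": stage_rg,
    "compare": stage_compare,
    "report": stage_report,
}


def run_stage(name: str, cfg: RunConfig, outdir=None) -> None:
    out = Path(outdir) if outdir is not None else Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    _STAGE_FUNCS[name](cfg, out)


def run_all(cfg: RunConfig, outdir=None) -> None:
    for name in STAGES:
        run_stage(name, cfg, outdir)
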