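"""End-to-end runs: input loading, harmonization, pruning, inference, outputs.

A run takes a marginal summary-statistics table plus a reference genotype
panel, intersects and allele-harmonizes the two, applies MAF and LD pruning
(defaults r2 <= 0.95, MAF >= 5%), reconstructs z = X'y, whitens per LD block,
and performs posterior model inference by enumeration or stochastic search.
Every dropped SNP is recorded in a manifest with its reason, so the analysed
and dropped sets exactly partition the input.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .effects import gibbs_effect_posterior
from .inference import (
    PriorSpec,
    bayes_factor_min_signals,
    enumerate_models,
)
from .ld import (
    build_blocks,
    center_genotype_matrix,
    partition_blocks,
    prune_snps,
    read_block_bed,
    read_reference_matrix,
    read_reference_vcf,
)
from .sampler import SamplerConfig, run_sampler
from .summary import (
    StrandAmbiguousError,
    harmonize_alleles,
    read_summary_stats,
    reconstruct_z,
)

__all__ = ["RunConfig", "load_inputs", "run_pipeline"]

log = logging.getLogger("jamss")


@dataclass
class RunConfig:
    """Configuration of one reproducible analysis run."""

    summary_path: str
    reference_path: str
    out_dir: str
    blocks_path: str | None = None
    engine: str = "enumerate"  # or "sample"
    a_sigma: float = 0.01
    b_sigma: float = 0.01
    tau: float | None = None
    a_omega: float = 1.0
    b_omega: float = 9.0
    max_dim: int = 3
    r2_max: float = 0.95
    maf_min: float = 0.05
    r2_between_max: float = 0.01
    iterations: int = 2_000_000
    burn_in_fraction: float = 0.5
    thin: int | None = None
    keep_ambiguous: bool = False
    seed: int = 0
    n_effect_draws: int = 10_000

    def __post_init__(self) -> None:
        if self.engine not in {"enumerate", "sample"}:
            raise ValueError(f"unknown engine {self.engine!r}")
        for name in ("r2_max", "maf_min"):
            if not (0.0 < getattr(self, name) <= 1.0):
                raise ValueError(f"{name} must lie in (0,1]")

    def prior(self) -> PriorSpec:
        return PriorSpec(
            a_sigma=self.a_sigma,
            b_sigma=self.b_sigma,
            tau=self.tau,
            a_omega=self.a_omega,
            b_omega=self.b_omega,
            max_dim=self.max_dim,
        )


def _read_reference(path: str):
    """Dispatch on extension: VCF or headered numeric/PLINK-style text."""
    p = Path(path)
    if p.suffix in {".vcf", ".gz"} or p.name.endswith(".vcf.gz"):
        dosages, meta = read_reference_vcf(p)
        return dosages, list(meta["SNP"]), meta
    dosages, ids = read_reference_matrix(p)
    return dosages, ids, None


def load_inputs(config: RunConfig):
    """Load, intersect, harmonize and prune the inputs.

    Returns (summaries, centred reference matrix, block boundaries, manifest).
    The manifest frame lists every input SNP with its fate (analysed, or a
    drop reason: missing-from-reference, strand-ambiguous, allele-mismatch,
    maf, ld-prune, zero-variance-in-reference).
    """
    summaries = read_summary_stats(config.summary_path)
    ids_seen = [s.snp_id for s in summaries]
    if len(set(ids_seen)) != len(ids_seen):
        dupes = sorted({x for x in ids_seen if ids_seen.count(x) > 1})
        raise ValueError(f"duplicated SNP ids in summary file: {dupes}")
    dosages, ref_ids, meta = _read_reference(config.reference_path)
    if len(set(ref_ids)) != len(ref_ids):
        raise ValueError("duplicated SNP ids in reference panel")
    ref_index = {s: j for j, s in enumerate(ref_ids)}

    manifest: dict[str, str] = {}
    harmonized = []
    cols = []
    for s in summaries:
        j = ref_index.get(s.snp_id)
        if j is None:
            manifest[s.snp_id] = "missing-from-reference"
            continue
        col = dosages[:, j]
        obs = col[~np.isnan(col)]
        if obs.size == 0 or np.all(obs == obs[0]):
            manifest[s.snp_id] = "zero-variance-in-reference"
            continue
        if meta is not None:
            ref_pair = (str(meta.iloc[j]["ALT"]), str(meta.iloc[j]["REF"]))
        else:
            ref_pair = (s.effect_allele, s.other_allele)  # no allele metadata: trust input
        try:
            h = harmonize_alleles(s, ref_pair, allow_ambiguous=config.keep_ambiguous)
        except StrandAmbiguousError:
            manifest[s.snp_id] = "strand-ambiguous"
            continue
        except ValueError:
            manifest[s.snp_id] = "allele-mismatch"
            continue
        if h.beta_hat != s.beta_hat:
            log.info("flipped allele orientation for %s", s.snp_id)
        harmonized.append(h)
        cols.append(j)

    if not harmonized:
        raise ValueError("zero overlapping SNPs between summary file and reference panel")

    # order by genomic position when available
    if meta is not None:
        keys = [(str(meta.iloc[j]["CHROM"]), int(meta.iloc[j]["POS"])) for j in cols]
        order = sorted(range(len(cols)), key=keys.__getitem__)
        harmonized = [harmonized[k] for k in order]
        cols = [cols[k] for k in order]

    sub = dosages[:, cols]
    centred = center_genotype_matrix(sub, [h.snp_id for h in harmonized])
    mafs = np.array([h.maf for h in harmonized])
    keep = prune_snps(centred, mafs, r2_max=config.r2_max, maf_min=config.maf_min)
    keep_set = set(keep)
    minor = np.minimum(mafs, 1 - mafs)
    for k, h in enumerate(harmonized):
        if k in keep_set:
            manifest[h.snp_id] = "analysed"
        elif minor[k] < config.maf_min:
            manifest[h.snp_id] = "maf"
        else:
            manifest[h.snp_id] = "ld-prune"
    harmonized = [harmonized[k] for k in keep]
    centred = centred[:, keep]
    centred = centred - centred.mean(axis=0)

    if config.blocks_path is not None:
        positions = (
            np.array([meta.iloc[cols[k]]["POS"] - 1 for k in keep])
            if meta is not None
            else np.arange(len(keep))
        )
        chroms = (
            np.array([meta.iloc[cols[k]]["CHROM"] for k in keep]) if meta is not None else None
        )
        boundaries = read_block_bed(config.blocks_path, positions, chroms)
    else:
        boundaries = partition_blocks(centred, config.r2_between_max)

    manifest_df = pd.DataFrame(
        {"SNP": list(manifest), "status": [manifest[s] for s in manifest]}
    )
    return harmonized, centred, boundaries, manifest_df


def run_pipeline(config: RunConfig) -> dict:
    """Execute a full analysis and write the result bundle to ``config.out_dir``.

    Outputs: models.tsv, snp_probabilities.tsv, bayes_factors.tsv,
    effects.tsv, snp_manifest.tsv and run_log.json (config echo, versions,
    per-block condition numbers).  Deterministic given config + seed.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summaries, centred, boundaries, manifest = load_inputs(config)
    n_study = summaries[0].n
    z = reconstruct_z(summaries)
    ids = [s.snp_id for s in summaries]
    blocks = build_blocks(centred, z, ids, n_study=n_study, boundaries=boundaries)
    prior = config.prior().resolve_tau(len(ids), n_study)

    if config.engine == "enumerate":
        table = enumerate_models(blocks, prior, n_study=n_study)
        result = table
        models_df = table.models_frame()
    else:
        samples = run_sampler(
            blocks,
            prior,
            SamplerConfig(
                n_iterations=config.iterations,
                burn_in_fraction=config.burn_in_fraction,
                seed=config.seed,
                thinning=config.thin,
            ),
        )
        result = samples
        models_df = _sampled_models_frame(samples)
        np.savetxt(out / "indicator_samples.tsv.txt", samples.indicators, fmt="%d", delimiter="\t")

    pips = result.snp_probabilities()
    bf_rows = []
    for k in (1, 2, 3):
        try:
            bf = bayes_factor_min_signals(result, k)
        except ValueError:
            continue
        bf_rows.append({"k": k, "bayes_factor": bf})

    # conditional effect posterior for the top non-empty model of each block
    effect_rows = []
    top = models_df[models_df["snps"] != "."].drop_duplicates("block", keep="first")
    for _, row in top.iterrows():
        wb = blocks[int(row["block"])]
        sel = row["snps"].split(",")
        idx = tuple(wb.block.snp_ids.index(s) for s in sel)
        post = gibbs_effect_posterior(
            wb.block.chol_upper,
            wb.z_whitened,
            idx,
            prior,
            n_draws=config.n_effect_draws,
            seed=config.seed,
            snp_ids=wb.block.snp_ids,
        )
        summ = post.summary()
        summ["model"] = row["snps"]
        effect_rows.append(summ)

    _write_tsv(models_df, out / "models.tsv")
    _write_tsv(
        pips.rename_axis("SNP").reset_index().rename(columns={0: "posterior_prob"}),
        out / "snp_probabilities.tsv",
    )
    _write_tsv(pd.DataFrame(bf_rows), out / "bayes_factors.tsv")
    if effect_rows:
        _write_tsv(pd.concat(effect_rows, ignore_index=True), out / "effects.tsv")
    _write_tsv(manifest, out / "snp_manifest.tsv")

    run_log = {
        "version": __version__,
        "config": asdict(config),
        "tau": prior.tau,
        "n_snps_analysed": len(ids),
        "blocks": [list(map(int, b)) for b in boundaries],
        "block_condition_numbers": [
            float(np.linalg.cond(wb.block.xtx)) for wb in blocks
        ],
    }
    (out / "run_log.json").write_text(json.dumps(run_log, indent=2, sort_keys=True))
    return {
        "result": result,
        "snp_probabilities": pips,
        "models": models_df,
        "manifest": manifest,
        "out_dir": str(out),
    }


def _sampled_models_frame(samples) -> pd.DataFrame:
    """Visited-model frequencies from the retained indicator rows, per block."""
    rows = []
    lo = 0
    n = len(samples.indicators)
    for b, ids in enumerate(samples.block_snp_ids):
        hi = lo + len(ids)
        sub = samples.indicators[:, lo:hi]
        uniq, counts = np.unique(sub, axis=0, return_counts=True)
        for g, c in zip(uniq, counts):
            sel = [ids[j] for j in np.flatnonzero(g)]
            rows.append(
                {
                    "block": b,
                    "snps": ",".join(sel) if sel else ".",
                    "size": len(sel),
                    "log_prior": np.nan,
                    "log_marginal_likelihood": np.nan,
                    "posterior_prob": c / n,
                }
            )
        lo = hi
    df = pd.DataFrame(rows).sort_values(
        by=["posterior_prob", "size", "snps"], ascending=[False, True, True], kind="stable"
    ).reset_index(drop=True)
    df.insert(0, "rank", np.arange(1, len(df) + 1))
    return df


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
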