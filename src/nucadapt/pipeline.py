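"""End-to-end orchestration: load -> shuffle -> composition -> rna -> stats
-> predictors -> report.

Every stage deposits plain TSV tables (with a provenance header: package
version, seed, config hash) into the run's output directory.  The report
layout mirrors the classic comparative-genomics presentation: per-group
weighted compositions, dinucleotide contrasts with significance tiers,
codon-position OGT correlations, mRNA folding phase spectra and purine
loads, and proteome OGT predictors.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .composition import (
    DINUCLEOTIDES,
    NUCLEOTIDES,
    aa_profile,
    dinuc_frequencies,
    dinucleotide_contrast,
    dipeptide_contrast,
    nuc_composition,
    ry_collapse,
)
from .genome_io import (
    GenomeDataset,
    build_correlation_cohort,
    build_oxygen_cohorts,
    classify_thermal_group,
    load_genomes,
    read_dataset_jsonl,
)
from .ogt_predictor import class_trend_correlations, profiles_to_matrix, search_predictor
from .rna_struct import (
    energy_summaries,
    fold_windows,
    phase_spectrum,
    region_purine_metrics,
)
from .shufflers import apply_null_model, make_dshfld
from .wstats import (
    WeightedSample,
    loop_stem_wilcoxon,
    ogt_correlation,
    one_sample_weighted_ttest,
    significance_tier,
    weighted_mean_var,
    weighted_welch_ttest,
)

log = logging.getLogger(__name__)

ALL_STAGES = ("shuffle", "composition", "rna", "stats", "predictors")


@dataclass
class RunConfig:
    """One pipeline run: inputs, stage toggles, folding settings, seed."""

    out_dir: str | Path = "nucadapt_run"
    dataset_path: str | Path | None = None
    fasta_dir: str | Path | None = None
    metadata_path: str | Path | None = None
    null_models: tuple[str, ...] = ("ncb", "shfld")
    stages: tuple[str, ...] = ALL_STAGES
    window: int = 50
    step: int = 10
    temperature: float = 37.0
    max_fold_genes: int = 2
    max_fold_windows: int = 5
    dshfld_sweeps: int = 30
    seed: int = 0

    def config_hash(self) -> str:
        payload = {
            k: str(v)
            for k, v in dataclasses.asdict(self).items()
            if k != "out_dir"
        }
        return hashlib.md5(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:12]


def _load(config: RunConfig, genomes: Sequence[GenomeDataset] | None) -> list[GenomeDataset]:
    if genomes is not None:
        return list(genomes)
    if config.dataset_path is not None:
        return read_dataset_jsonl(config.dataset_path)
    if config.fasta_dir is not None and config.metadata_path is not None:
        return load_genomes(config.fasta_dir, config.metadata_path)
    raise ValueError("no input: pass genomes, dataset_path or fasta_dir+metadata_path")


def _write_table(df: pd.DataFrame, path: Path, config: RunConfig) -> None:
    header = (
        f"# nucadapt {__version__}\n"
        f"# seed={config.seed} config={config.config_hash()}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, sep="\t", index=False, na_rep="NA", float_format="%.6g")


def _group_keys(g: GenomeDataset) -> dict[str, str]:
    return {
        "domain": g.metadata.domain,
        "thermal": classify_thermal_group(g.metadata.ogt),
        "oxygen": g.metadata.oxygen,
    }


_COMBOS = {"(A+T)": "AT", "(A+G)": "AG", "(T+G)": "TG", "(G+C)": "GC", "(A+C)": "AC"}


def _per_genome_composition(
    g: GenomeDataset, variants: dict[str, list[str]]
) -> dict[str, float]:
    """Flat statistic -> value map for one genome.

    Keys look like ``cds_nat/pos3/G``, ``cds_ncb/gc3``, ``trna/whole/G``,
    ``cds_nat/dct_any/AG``, ``cds_nat/dct_3-1/RpR``.
    """
    out: dict[str, float] = {}
    seq_sets: dict[str, list[str]] = {
        "cds_nat": g.cds,
        **{f"cds_{m}": seqs for m, seqs in variants.items()},
        "ncdna": g.ncdna,
        "trna": g.trna,
        "rrna": g.rrna,
    }
    for name, seqs in seq_sets.items():
        if not seqs:
            continue
        comp = nuc_composition(seqs, "whole")
        for nt in NUCLEOTIDES:
            out[f"{name}/whole/{nt}"] = comp.freqs[nt]
        out[f"{name}/whole/(G+C)"] = comp.freqs["G"] + comp.freqs["C"]
        contrast = dinucleotide_contrast(dinuc_frequencies(seqs, "any"))
        for d in DINUCLEOTIDES:
            if d in contrast.contrasts:
                out[f"{name}/dct_any/{d[0]}p{d[1]}"] = contrast.contrasts[d]
        if not name.startswith("cds"):
            continue
        for k in (1, 2, 3):
            comp = nuc_composition(seqs, f"codon-pos-{k}")
            for nt in NUCLEOTIDES:
                out[f"{name}/pos{k}/{nt}"] = comp.freqs[nt]
            for label, letters in _COMBOS.items():
                out[f"{name}/pos{k}/{label}"] = sum(comp.freqs[nt] for nt in letters)
        out[f"{name}/gc3"] = out[f"{name}/pos3/(G+C)"]
        for junction in ("1-2", "2-3", "3-1"):
            table = dinuc_frequencies(seqs, junction)
            dct = dinucleotide_contrast(table)
            for d in DINUCLEOTIDES:
                if d in dct.contrasts:
                    out[f"{name}/dct_{junction}/{d[0]}p{d[1]}"] = dct.contrasts[d]
            ry = ry_collapse(table)
            for cls, v in ry.contrasts.items():
                out[f"{name}/dct_{junction}/{cls}"] = v
    return out


def run_pipeline(
    config: RunConfig, genomes: Sequence[GenomeDataset] | None = None
) -> dict[str, pd.DataFrame]:
    """Execute the configured stages and write the report tables.

    Returns the report bundle (table name -> DataFrame).  Stage isolation:
    disabling one stage removes its tables without altering the others'
    numbers; reruns with the same inputs and seed are byte-identical.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    genomes = _load(config, genomes)
    log.info("loaded %d genomes", len(genomes))
    bundle: dict[str, pd.DataFrame] = {}

    # ---- shuffle
    variants_by_genome: dict[str, dict[str, list[str]]] = {}
    if "shuffle" in config.stages:
        for g in genomes:
            variants_by_genome[g.metadata.genome_id] = {
                m: apply_null_model(g, m, rng, max_sweeps=config.dshfld_sweeps)
                for m in config.null_models
                if m != "dshfld"  # dShfld is folded lazily in the rna stage
            }

    # ---- composition
    per_genome: pd.DataFrame | None = None
    if "composition" in config.stages:
        rows = {}
        for g in genomes:
            rows[g.metadata.genome_id] = _per_genome_composition(
                g, variants_by_genome.get(g.metadata.genome_id, {})
            )
        per_genome = pd.DataFrame.from_dict(rows, orient="index").sort_index()
        bundle["per_genome_statistics"] = per_genome.reset_index(names="genome_id")

    meta = {g.metadata.genome_id: g for g in genomes}
    sizes = {gid: float(g.metadata.genome_size) for gid, g in meta.items()}
    ogts = {gid: g.metadata.ogt for gid, g in meta.items()}
    cohort_ids = [g.metadata.genome_id for g in build_correlation_cohort(genomes)]

    # ---- rna
    if "rna" in config.stages:
        bundle.update(
            _rna_stage(config, genomes, rng, ogts, cohort_ids)
        )

    # ---- stats
    if "stats" in config.stages and per_genome is not None:
        bundle.update(
            _stats_stage(per_genome, meta, sizes, ogts, cohort_ids, genomes)
        )

    # ---- predictors
    if "predictors" in config.stages:
        bundle.update(_predictor_stage(genomes, cohort_ids))

    # ---- report
    for name, df in bundle.items():
        _write_table(df, out_dir / f"{name}.tsv", config)
    log.info("wrote %d tables to %s", len(bundle), out_dir)
    return bundle


def _rna_stage(
    config: RunConfig,
    genomes: Sequence[GenomeDataset],
    rng: np.random.Generator,
    ogts: dict[str, float],
    cohort_ids: list[str],
) -> dict[str, pd.DataFrame]:
    phase_rows = []
    purine_rows = []
    energy_cols: dict[str, dict[str, float]] = {}
    loop_ag: dict[str, float] = {}
    stem_ag: dict[str, float] = {}
    for g in genomes:
        gid = g.metadata.genome_id
        genes = [c for c in g.cds if len(c) >= config.window][: config.max_fold_genes]
        if not genes:
            continue
        nat_windows = []
        ctrl_windows = []
        for k, cds in enumerate(genes):
            nat_windows += fold_windows(
                cds, gene_id=f"{gid}|g{k}", window=config.window,
                step=config.step, max_windows=config.max_fold_windows,
            )
            ctrl = make_dshfld(cds, rng, max_sweeps=config.dshfld_sweeps)
            ctrl_windows += fold_windows(
                ctrl, gene_id=f"{gid}|g{k}|dshfld", window=config.window,
                step=config.step, max_windows=config.max_fold_windows,
            )
        spec_nat = phase_spectrum(nat_windows)
        spec_ctrl = phase_spectrum(ctrl_windows)
        e_sg, e_bp = energy_summaries(nat_windows)
        ec_sg, ec_bp = energy_summaries(ctrl_windows)
        energy_cols[gid] = {
            "E_sg": e_sg,
            "E_bp": e_bp if e_bp is not None else np.nan,
            "E_sg_over_dshfld": e_sg / ec_sg if ec_sg else np.nan,
            "E_bp_over_dshfld": (
                e_bp / ec_bp if e_bp is not None and ec_bp not in (None, 0) else np.nan
            ),
        }
        for ph in ("I", "II", "III"):
            top = bottom = "NA"
            if spec_nat.counts[ph]:
                top, bottom = spec_nat.extremes(ph)
            phase_rows.append(
                {
                    "genome_id": gid,
                    "domain": g.metadata.domain,
                    "thermal": classify_thermal_group(g.metadata.ogt),
                    "phase": ph,
                    "n_pairs_nat": spec_nat.totals[ph],
                    "n_pairs_dshfld": spec_ctrl.totals[ph],
                    "most_frequent": top,
                    "least_frequent": bottom,
                }
            )
        try:
            lm = region_purine_metrics(nat_windows, "loop")
            sm = region_purine_metrics(nat_windows, "stem")
        except ValueError:
            continue
        loop_ag[gid] = lm.ag_fraction
        stem_ag[gid] = sm.ag_fraction
        for region, m in (("loop", lm), ("stem", sm)):
            purine_rows.append(
                {
                    "genome_id": gid,
                    "region": region,
                    "A+G": m.ag_fraction,
                    "R/Y": m.ry_ratio if m.ry_ratio is not None else np.nan,
                    "ApG": m.apg_frequency,
                    **m.codon_class_freqs,
                }
            )
    out: dict[str, pd.DataFrame] = {}
    out["rna_phases"] = pd.DataFrame(phase_rows)
    out["rna_purine"] = pd.DataFrame(purine_rows)
    energies = pd.DataFrame.from_dict(energy_cols, orient="index").sort_index()
    rows = []
    ids = [gid for gid in cohort_ids if gid in energies.index]
    for col in energies.columns:
        vals = energies.loc[ids, col].dropna()
        if len(vals) >= 3 and np.ptp(vals.to_numpy()) > 0:
            res = ogt_correlation(vals.to_numpy(), [ogts[i] for i in vals.index])
            rows.append(
                {"statistic": col, "r": res.r, "n": res.n, "p": res.p, "tier": res.tier}
            )
    if len(loop_ag) >= 6:
        common = sorted(set(loop_ag) & set(stem_ag))
        p = loop_stem_wilcoxon(
            [loop_ag[i] for i in common], [stem_ag[i] for i in common]
        )
        rows.append(
            {
                "statistic": "A+G loop-vs-stem (Wilcoxon)",
                "r": np.nan,
                "n": len(common),
                "p": p,
                "tier": significance_tier(p),
            }
        )
    out["rna_energies"] = energies.reset_index(names="genome_id")
    out["rna_correlations"] = pd.DataFrame(rows)
    return out


def _stats_stage(
    per_genome: pd.DataFrame,
    meta: dict[str, GenomeDataset],
    sizes: dict[str, float],
    ogts: dict[str, float],
    cohort_ids: list[str],
    genomes: Sequence[GenomeDataset],
) -> dict[str, pd.DataFrame]:
    rows = []
    domains = sorted({g.metadata.domain for g in genomes})
    for stat in per_genome.columns:
        null_value = 1.0 if "/dct_" in stat else 0.25
        for domain in domains:
            ids = [
                gid for gid in per_genome.index
                if meta[gid].metadata.domain == domain
                and not np.isnan(per_genome.at[gid, stat])
            ]
            if len(ids) < 2:
                continue
            sample = WeightedSample(
                per_genome.loc[ids, stat].to_numpy(), [sizes[i] for i in ids]
            )
            test = one_sample_weighted_ttest(sample, null_value)
            mean, _ = weighted_mean_var(sample)
            row = {
                "domain": domain,
                "statistic": stat,
                "weighted_mean": mean,
                "h0": null_value,
                "t": test.t,
                "p": test.p,
                "tier": test.tier,
                "n": len(ids),
            }
            cids = [i for i in ids if i in cohort_ids]
            vals = per_genome.loc[cids, stat].to_numpy()
            if len(cids) >= 3 and np.ptp(vals) > 0:
                corr = ogt_correlation(vals, [ogts[i] for i in cids])
                row.update({"ogt_r": corr.r, "ogt_p": corr.p, "ogt_tier": corr.tier})
            else:
                row.update({"ogt_r": np.nan, "ogt_p": np.nan, "ogt_tier": "NA"})
            rows.append(row)
    tables = {"group_statistics": pd.DataFrame(rows)}

    # aerobic vs anaerobic (G+C)3, natural and codon-bias-free
    aer, anaer = build_oxygen_cohorts(list(genomes))
    gc3_rows = []
    for stat in ("cds_nat/gc3", "cds_ncb/gc3"):
        if stat not in per_genome.columns:
            continue
        a_ids = [g.metadata.genome_id for g in aer if g.metadata.genome_id in per_genome.index]
        b_ids = [g.metadata.genome_id for g in anaer if g.metadata.genome_id in per_genome.index]
        if len(a_ids) < 2 or len(b_ids) < 2:
            continue
        a = WeightedSample(per_genome.loc[a_ids, stat].to_numpy(), [sizes[i] for i in a_ids])
        b = WeightedSample(per_genome.loc[b_ids, stat].to_numpy(), [sizes[i] for i in b_ids])
        res = weighted_welch_ttest(a, b)
        gc3_rows.append(
            {
                "statistic": stat,
                "aerobe_mean": weighted_mean_var(a)[0],
                "anaerobe_mean": weighted_mean_var(b)[0],
                "gap": weighted_mean_var(a)[0] - weighted_mean_var(b)[0],
                "t": res.t,
                "df": res.df,
                "p": res.p,
                "tier": res.tier,
                "n_aerobe": a.n,
                "n_anaerobe": b.n,
            }
        )
    tables["gc3_aerobicity"] = pd.DataFrame(gc3_rows)
    return tables


def _predictor_stage(
    genomes: Sequence[GenomeDataset], cohort_ids: list[str]
) -> dict[str, pd.DataFrame]:
    rows = []
    by_domain: dict[str, list[GenomeDataset]] = {}
    for g in genomes:
        if g.metadata.genome_id in cohort_ids:
            by_domain.setdefault(g.metadata.domain, []).append(g)
    by_domain["All"] = [g for g in genomes if g.metadata.genome_id in cohort_ids]
    for domain, members in sorted(by_domain.items()):
        if len(members) < 8:
            continue
        profiles = [aa_profile(g.proteins()) for g in members]
        freq = profiles_to_matrix(
            profiles, index=[g.metadata.genome_id for g in members]
        )
        ogts = [g.metadata.ogt for g in members]
        model = search_predictor(freq, ogts, max_set_size=5, strategy="greedy")
        dip_rows = []
        for g in members:
            _, classes = dipeptide_contrast(g.proteins())
            dip_rows.append(classes)
        dip = pd.DataFrame(dip_rows, index=freq.index)
        trends = class_trend_correlations(freq, ogts, dipeptide_class_matrix=dip)
        row = {
            "domain": domain,
            "n": len(members),
            "predictor_set": "".join(model.amino_acid_set),
            "predictor_r": model.r,
        }
        for key, res in trends.items():
            row[f"r_{key}"] = res.r
            row[f"tier_{key}"] = res.tier
        rows.append(row)
    return {"predictors": pd.DataFrame(rows)}
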