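"""End-to-end orchestration: inputs -> traits -> transformations -> structure
-> association (LMM, logistic MM, SKAT) -> ART -> thresholds -> peaks ->
genes -> TSV outputs plus an audit log.

Every stage is driven by a single config mapping (YAML-loadable) and a seed;
outputs are plain TSV/JSON written with fixed float formatting so reruns are
byte-identical, including across SKAT worker counts.
"""

from __future__ import annotations

import json
import os

import numpy as np
import pandas as pd
import yaml

from . import io as rio
from .art import (art_anchor_scan, art_bonferroni_threshold, art_two_round_gmmat,
                  art_windows_frame, conservative_bonferroni)
from .glmm import LogisticMixedGWAS
from .lmm import LinearMixedGWAS
from .popstruct import GenotypePCA, compute_grm
from .prep import dichotomize, transform_trait
from .simulate import (SimulationConfig, make_annotation, simulate_genotypes,
                       simulate_traits)
from .skat import WindowSKAT
from .postgwas import call_peaks, summarize_tiers
from .traits import merge_replicates

_FLOAT_FMT = "%.10g"


def default_config() -> dict:
    """Desk-scale demonstration configuration with one planted causal SNP."""
    return {
        "simulate": {
            "n_samples": 200, "n_snps": 1000, "n_subpops": 4, "fst": 0.1,
            "h2_poly": 0.3, "zero_threshold": -0.5,
            "causal_loci": [[120, 0.45]],
            "chrom_lengths": {"Chr01": 500_000, "Chr02": 500_000},
        },
        "annotation": {"n_genes_per_chrom": 25},
        "structure": {"n_pcs": 5},
        "analyses": [
            {"name": "callus_wk4_boxcox", "trait": "callus_area",
             "timepoint": 4, "method": "lmm", "transform": "boxcox"},
            {"name": "callus_wk4_rbinv", "trait": "callus_area",
             "timepoint": 4, "method": "lmm", "transform": "rbinv"},
            {"name": "callus_wk2_dichot", "trait": "callus_area",
             "timepoint": 2, "method": "glmm"},
            {"name": "callus_wk4_untransformed", "trait": "callus_area",
             "timepoint": 4, "method": "skat"},
        ],
        "thresholds": {"alpha": 0.05, "fdr_q": 0.10, "anchor_p": 1e-5,
                       "neighbor_p": 1e-4, "anchor_radius": 500,
                       "min_neighbors": 5, "peak_radius": 30_000,
                       "art_window_bp": 1000},
        "skat": {"width": 3000, "step": 1000, "p_threshold": 1e-3,
                 "b_stages": [1000, 5000]},
        "filters": {"maf_min": 0.05, "max_missing": 0.10},
    }


def _load_config(config) -> dict:
    if config is None:
        return default_config()
    if isinstance(config, (str, os.PathLike)):
        with open(config) as fh:
            return yaml.safe_load(fh)
    return dict(config)


def _covariate_frame(merged: pd.DataFrame, ids) -> pd.DataFrame:
    per_geno = (merged.groupby("genotype_id")
                .agg(diameter=("diameter", "first"), phase=("phase", "first")))
    per_geno = per_geno.loc[ids]
    out = pd.DataFrame(index=per_geno.index)
    out["diameter"] = per_geno["diameter"].astype(float)
    out["phase"] = pd.Categorical(per_geno["phase"].astype(int))
    return out


def run_pipeline(config=None, out_dir: str = "results", seed: int = 0,
                 n_workers: int = 1) -> dict:
    """Run the full analysis on (by default) a simulated study.

    Returns a dict of the in-memory result tables; writes TSVs and
    ``audit.json`` under ``out_dir``.
    """
    cfg = _load_config(config)
    os.makedirs(out_dir, exist_ok=True)
    audit = {"seed": seed}

    sim_kwargs = dict(cfg.get("simulate", {}))
    sim_kwargs["causal_loci"] = tuple(
        (int(j), float(b)) for j, b in sim_kwargs.get("causal_loci", []))
    sim = SimulationConfig(seed=seed, **sim_kwargs)
    G = simulate_genotypes(sim)
    table = simulate_traits(G, sim)
    ann = make_annotation(sim.chrom_lengths,
                          n_genes_per_chrom=cfg.get("annotation", {})
                          .get("n_genes_per_chrom", 25), seed=seed)
    audit["n_samples"] = G.n_samples
    audit["n_snps"] = G.n_snps

    merged = merge_replicates(table)
    rio.write_traits_csv(merged, os.path.join(out_dir, "traits_merged.csv"))

    kin = compute_grm(G, maf_min=cfg.get("filters", {}).get("maf_min", 0.05))
    rio.write_kinship(kin, os.path.join(out_dir, "kinship.tsv"))
    pcs = GenotypePCA(n_components=cfg.get("structure", {}).get("n_pcs", 5)) \
        .fit_transform(G)

    filters = cfg.get("filters", {})
    thr_cfg = cfg.get("thresholds", {})
    alpha = thr_cfg.get("alpha", 0.05)
    genome_bp = float(sum(sim.chrom_lengths.values()))
    art_thr = art_bonferroni_threshold(genome_bp,
                                       thr_cfg.get("art_window_bp", 1000),
                                       alpha)
    audit["art_bonferroni_threshold"] = art_thr

    ids = list(G.sample_ids)
    covs = _covariate_frame(merged, ids)
    assoc_frames, peak_frames = [], []
    audit["analyses"] = {}

    for ana in cfg.get("analyses", []):
        name, method = ana["name"], ana["method"]
        sub = merged[merged["timepoint"] == ana.get("timepoint", 4)]
        y_raw = sub.set_index("genotype_id")[ana["trait"]].reindex(ids)
        entry = {"method": method, "n_input": int(y_raw.notna().sum())}

        if method == "lmm":
            vals, kept, tf_audit = transform_trait(
                y_raw.to_numpy(float), method=ana.get("transform", "boxcox"))
            y = pd.Series(vals, index=[ids[i] for i in kept])
            est = LinearMixedGWAS(maf_min=filters.get("maf_min", 0.05),
                                  max_missing=filters.get("max_missing", 0.10))
            est.fit(G, y, covariates=covs, kinship=kin, trait=name)
            res = est.results_.assign(trait=name)
            entry.update({"transform": tf_audit, "h2_snp": est.null_.h2_snp,
                          "passes_h2_screen": est.passes_screen_,
                          "n_tests": len(res)})
            assoc_frames.append(res)
            cons = conservative_bonferroni(len(res), alpha)
            windows = art_anchor_scan(
                res, anchor_p=thr_cfg.get("anchor_p", 1e-5),
                neighbor_p=thr_cfg.get("neighbor_p", 1e-4),
                radius=thr_cfg.get("anchor_radius", 500),
                min_neighbors=thr_cfg.get("min_neighbors", 5))
            art_df = art_windows_frame(windows, art_thr).assign(trait=name)
            art_df.to_csv(os.path.join(out_dir, f"art_{name}.tsv"), sep="\t",
                          index=False, float_format=_FLOAT_FMT)
            peak_frames.append(call_peaks(
                res, ann, {"conservative_bonferroni": cons,
                           "fdr_q": thr_cfg.get("fdr_q", 0.10)},
                method=f"lmm:{name}",
                radius=thr_cfg.get("peak_radius", 30_000)))
            if len(art_df):
                art_assoc = art_df.rename(columns={"p_combined": "p"})
                art_assoc["pos"] = ((art_assoc["window_start"]
                                     + art_assoc["window_end"]) // 2)
                peak_frames.append(call_peaks(
                    art_assoc[["chrom", "pos", "p"]], ann,
                    {"art_bonferroni": art_thr, "fdr_q": 1e-300},
                    method=f"lmm-art:{name}",
                    radius=thr_cfg.get("peak_radius", 30_000)))
            entry["n_art_windows"] = len(art_df)

        elif method == "glmm":
            y = pd.Series(dichotomize(y_raw.dropna().to_numpy(float)),
                          index=y_raw.dropna().index)
            est = LogisticMixedGWAS(maf_min=filters.get("maf_min", 0.05),
                                    max_missing=filters.get("max_missing", 0.10))
            est.fit(G, y, covariates=covs, kinship=kin, trait=name)
            res = est.results_.assign(trait=name)
            entry.update({"h2_snp": est.null_.h2_snp, "n_tests": len(res)})
            assoc_frames.append(res)
            cons = conservative_bonferroni(len(res), alpha)

            def wald_cb(keys, est=est):
                df = est.wald_refit(keys)
                return {(r["chrom"], int(r["pos"])): r["p"]
                        for _, r in df.iterrows()}

            r1, r2 = art_two_round_gmmat(
                res, wald_cb, art_thr,
                anchor_p=thr_cfg.get("anchor_p", 1e-5),
                neighbor_p=thr_cfg.get("neighbor_p", 1e-4),
                radius=thr_cfg.get("anchor_radius", 500),
                min_neighbors=thr_cfg.get("min_neighbors", 5))
            r1.assign(trait=name).to_csv(
                os.path.join(out_dir, f"art_{name}_round1.tsv"), sep="\t",
                index=False, float_format=_FLOAT_FMT)
            r2.assign(trait=name).to_csv(
                os.path.join(out_dir, f"art_{name}_round2.tsv"), sep="\t",
                index=False, float_format=_FLOAT_FMT)
            peak_frames.append(call_peaks(
                res, ann, {"conservative_bonferroni": cons,
                           "fdr_q": thr_cfg.get("fdr_q", 0.10)},
                method=f"glmm:{name}",
                radius=thr_cfg.get("peak_radius", 30_000)))
            entry["n_art_round1"] = len(r1)
            entry["n_art_round2_pass"] = int(r2["pass_threshold"].sum()) if len(r2) else 0

        elif method == "skat":
            mask = y_raw.notna().to_numpy()
            rows = np.flatnonzero(mask)
            Gs = type(G)(G.dosages[rows], G.chrom, G.pos,
                         [ids[i] for i in rows],
                         None if G.subpop is None else G.subpop[rows])
            Gs = Gs.filtered(maf_min=0.0)
            Xc = pd.get_dummies(covs.iloc[rows], drop_first=True, dtype=float)
            Xc = np.column_stack([Xc.to_numpy(float), pcs[rows]])
            sk_cfg = cfg.get("skat", {})
            est = WindowSKAT(width=sk_cfg.get("width", 3000),
                             step=sk_cfg.get("step", 1000),
                             p_threshold=sk_cfg.get("p_threshold", 1e-3),
                             b_stages=tuple(sk_cfg.get("b_stages",
                                                       (1000, 10_000, 100_000))),
                             n_workers=n_workers, seed=seed)
            est.fit(Gs, y_raw.to_numpy(float)[rows], covariates=Xc)
            res = est.results_.assign(trait=name)
            res.to_csv(os.path.join(out_dir, f"skat_{name}.tsv"), sep="\t",
                       index=False, float_format=_FLOAT_FMT)
            entry["n_windows"] = len(res)
            win_bonf = conservative_bonferroni(max(len(res), 1), alpha)
            sk_assoc = res.copy()
            sk_assoc["pos"] = (sk_assoc["start"] + sk_assoc["end"]) // 2
            sk_assoc["p"] = sk_assoc["p_emp"].fillna(sk_assoc["p_param"])
            peak_frames.append(call_peaks(
                sk_assoc[["chrom", "pos", "p"]], ann,
                {"conservative_bonferroni": win_bonf,
                 "fdr_q": thr_cfg.get("fdr_q", 0.10)},
                method=f"skat:{name}",
                radius=thr_cfg.get("peak_radius", 30_000)))
        else:
            raise ValueError(f"unknown analysis method {method!r}")
        audit["analyses"][name] = entry

    assoc = (pd.concat(assoc_frames, ignore_index=True)
             if assoc_frames else pd.DataFrame())
    if len(assoc):
        assoc = assoc.sort_values(["trait", "chrom", "pos"], ignore_index=True)
        assoc.to_csv(os.path.join(out_dir, "assoc.tsv"), sep="\t", index=False,
                     float_format=_FLOAT_FMT)
    peak_frames = [f for f in peak_frames if len(f)]
    peaks = (pd.concat(peak_frames, ignore_index=True)
             if peak_frames else pd.DataFrame(
                 columns=["chrom", "pos", "p", "method", "tier", "gene_id",
                          "relation", "tss_distance", "within_5kb"]))
    if len(peaks):
        peaks = peaks.sort_values(["method", "chrom", "pos"], ignore_index=True)
    peaks.to_csv(os.path.join(out_dir, "peaks.tsv"), sep="\t", index=False,
                 float_format=_FLOAT_FMT)
    tiers = summarize_tiers(peaks)
    tiers.to_csv(os.path.join(out_dir, "tier_summary.tsv"), sep="\t",
                 index=False)
    audit["n_peaks"] = len(peaks)
    with open(os.path.join(out_dir, "audit.json"), "w") as fh:
        json.dump(audit, fh, indent=2, sort_keys=True, default=float)
    return {"genotypes": G, "traits": merged, "assoc": assoc, "peaks": peaks,
            "tiers": tiers, "annotation": ann, "audit": audit}
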