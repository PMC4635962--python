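"""End-to-end orchestration: simulate -> QC -> kinship -> variance components
-> additive scan -> interaction scan -> partition, with one base seed, a
config hash stamped on every output, and a machine-readable summary."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from crossvar import io
from crossvar.kinship import build_kinship_set
from crossvar.partition import anova_effect_sizes, captured_additive, interaction_partition
from crossvar.power import ALPHA_ADDITIVE, ALPHA_INTERACTION, PowerQuery, qtl_power
from crossvar.qc import dedup_markers, filter_segregants
from crossvar.reml import ModelSpec, fit_aireml
from crossvar.scan_additive import _derive_seed, forward_search, qtl_table
from crossvar.scan_epistasis import (
    classify_peaks,
    fdr_select,
    full_scan,
    interaction_residuals,
    interaction_table,
)
from crossvar.simulate import (
    ArchitectureSpec,
    default_marker_map,
    simulate_genotypes,
    simulate_phenotypes,
)

log = logging.getLogger("crossvar")

__all__ = ["RunConfig", "run_all"]


@dataclass
class RunConfig:
    """Flat per-stage configuration for one reproducible run."""

    # simulation
    n_markers: int = 2000
    n_chromosomes: int = 16
    n_segregants: int = 800
    expected_crossovers: float = 65.0
    n_additive_qtl: int = 20
    n_interactions: int = 10
    h2_additive: float = 0.45
    H2_total: float = 0.55
    strain_var: float = 0.08
    n_replicates: int = 2
    # scans
    n_perm: int = 300
    alpha: float = 0.05
    fdr: float = 0.10
    min_separation: int = 50
    n_perm_fdr: int = 5
    # bookkeeping
    seed: int = 0
    out_dir: str = "crossvar_run"
    trait: str = "trait"

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def run_all(config: RunConfig, write_outputs: bool = True) -> dict:
    """Execute every stage in dependency order; returns the summary dict.

    Identical configs (hence identical config hashes and seeds) produce
    identical outputs.
    """
    t0 = time.time()
    chash = config.config_hash()
    out = Path(config.out_dir)
    if write_outputs:
        out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"config_hash": chash, "seed": config.seed, "stages": {}}

    def stage(name):
        summary["stages"][name] = {"t_start": round(time.time() - t0, 2)}
        log.info("stage %s (config %s)", name, chash)
        return time.time()

    # --- simulate -----------------------------------------------------
    t = stage("simulate")
    mmap = default_marker_map(config.n_markers, config.n_chromosomes)
    G = simulate_genotypes(
        mmap,
        config.n_segregants,
        config.expected_crossovers,
        seed=_derive_seed(config.seed, "genotypes"),
    )
    arch = ArchitectureSpec(
        n_additive_qtl=config.n_additive_qtl,
        n_interactions=config.n_interactions,
        h2_additive=config.h2_additive,
        H2_total=config.H2_total,
        strain_var=config.strain_var,
        n_replicates=config.n_replicates,
        seed=_derive_seed(config.seed, "phenotypes"),
    )
    pheno, truth = simulate_phenotypes(G, arch)
    summary["stages"]["simulate"]["seconds"] = round(time.time() - t, 2)

    # --- qc -----------------------------------------------------------
    t = stage("qc")
    report = filter_segregants(G)
    G = G.subset_segregants(report.kept_segregants)
    keep_obs = np.isin(pheno.strain, report.kept_segregants)
    relabel = {old: new for new, old in enumerate(report.kept_segregants)}
    strain = np.array([relabel[s] for s in pheno.strain[keep_obs]])
    y = pheno.value[keep_obs]
    G = dedup_markers(G)
    n = G.n_segregants
    summary["qc"] = {
        "n_kept_segregants": int(n),
        "n_dropped": len(report.dropped),
        "n_markers": int(G.n_markers),
    }
    summary["stages"]["qc"]["seconds"] = round(time.time() - t, 2)

    # --- kinship ------------------------------------------------------
    t = stage("kinship")
    kin = build_kinship_set(G)
    summary["stages"]["kinship"]["seconds"] = round(time.time() - t, 2)

    # --- variance components -----------------------------------------
    t = stage("variance_components")
    vc_fit = fit_aireml(
        ModelSpec(y=y, strain=strain, n_strains=n, K={"additive": kin.A, "interaction": kin.AA})
    )
    summary["variance_components"] = {
        "fractions": vc_fit.fractions,
        "fractions_se": vc_fit.fractions_se,
        "converged": vc_fit.converged,
    }
    summary["stages"]["variance_components"]["seconds"] = round(time.time() - t, 2)

    # --- additive scan ------------------------------------------------
    t = stage("scan_additive")
    qtl = forward_search(
        y,
        strain,
        n,
        kin,
        G,
        n_perm=config.n_perm,
        alpha=config.alpha,
        seed=config.seed,
        trait=config.trait,
    )
    peaks = [q.peak_marker for q in qtl]
    summary["scan_additive"] = {"n_qtl": len(qtl)}
    summary["stages"]["scan_additive"]["seconds"] = round(time.time() - t, 2)

    # --- interaction scan ---------------------------------------------
    t = stage("scan_epistasis")
    y_r = interaction_residuals(y, strain, n, kin)
    obs_peaks = full_scan(G, y_r, min_separation=config.min_separation, trait=config.trait)
    thr, sig = fdr_select(
        obs_peaks,
        G,
        y_r,
        n_perm=config.n_perm_fdr,
        target_fdr=config.fdr,
        seed=config.seed,
        min_separation=config.min_separation,
        trait=config.trait,
    )
    classify_peaks(sig, peaks, min_separation=config.min_separation)
    sig_pairs = [(p.marker_j, p.marker_k) for p in sig]
    summary["scan_epistasis"] = {
        "n_significant_pairs": len(sig),
        "lod_threshold": thr,
        "classification": {
            c: sum(p.classification == c for p in sig) for c in ("both", "one", "neither")
        },
    }
    summary["stages"]["scan_epistasis"]["seconds"] = round(time.time() - t, 2)

    # --- partition ----------------------------------------------------
    t = stage("partition")
    if peaks:
        cap = captured_additive(y, strain, n, G, peaks)
        part = interaction_partition(y, strain, n, G, kin, peaks, sig_pairs)
        summary["partition"] = {**cap, **part}
        counts = np.bincount(strain, minlength=n).astype(float)
        y_avg = np.bincount(strain, weights=y, minlength=n) / np.maximum(counts, 1)
        Gd = G.dosage()
        pair_cols = (
            Gd[:, [p[0] for p in sig_pairs]] * Gd[:, [p[1] for p in sig_pairs]]
            if sig_pairs
            else None
        )
        eff = anova_effect_sizes(y_avg, Gd[:, peaks], pair_cols)
        summary["effect_sizes"] = {
            "median_qtl_fraction": float(
                np.median(eff.loc[eff.term.str.startswith("qtl"), "fraction"])
            ),
            "median_pair_fraction": (
                float(np.median(eff.loc[eff.term.str.startswith("pair"), "fraction"]))
                if sig_pairs
                else None
            ),
        }
        for q, (_, row) in zip(qtl, eff.iterrows()):
            q.variance_explained = float(row["fraction"])
    else:
        summary["partition"] = {}
        summary["effect_sizes"] = {}
    summary["stages"]["partition"]["seconds"] = round(time.time() - t, 2)

    # --- power --------------------------------------------------------
    summary["power"] = {
        "additive_q0.005": qtl_power(PowerQuery(4390, 0.005, ALPHA_ADDITIVE)),
        "interaction_q0.008": qtl_power(PowerQuery(4390, 0.008, ALPHA_INTERACTION)),
    }

    summary["truth"] = {"realized_fractions": truth.realized_fractions}
    summary["wall_seconds"] = round(time.time() - t0, 2)

    if write_outputs:
        io.write_marker_map(G.map, out / f"markers.{chash}.tsv")
        io.write_phenotypes(
            type(pheno)(strain, pheno.replicate[keep_obs], y, n), out / f"phenotypes.{chash}.tsv"
        )
        qtl_table(qtl).to_csv(out / f"qtl.{chash}.tsv", sep="\t", index=False)
        interaction_table(sig, G).to_csv(
            out / f"interactions.{chash}.tsv", sep="\t", index=False
        )
        io.write_json(summary, out / f"summary.{chash}.json")
    return summary
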