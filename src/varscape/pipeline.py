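"""End-to-end pipeline orchestration over synthetic or user inputs.

A run is a pure function of its YAML-style config dict: one global seed
fans out to per-stage seeds through ``numpy.random.SeedSequence(seed)
.spawn``, every stage writes TSV/JSON into the run directory, and a
resolved copy of the config (plus its hash) is stored alongside so a rerun
with the same config is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import depletion, hotspots, mixture, segments, sharing, simulate, \
    spectra, variant_io

STAGES = ["genotypes", "singletons", "mixture", "spectra", "hotspots",
          "sharing", "depletion", "segments"]

DEFAULT_CONFIG = {
    "seed": 1,
    "stages": list(STAGES),
    "genotypes": {"n_sites": 800, "groups": {"A": 12, "B": 12},
                  "within_group_fraction": 0.3},
    "mixture": {"preset": "paperlike", "n": 20000, "k_max": 6,
                "alpha": 0.01, "tol": 1e-8, "max_iter": 2000, "restarts": 2},
    "hotspots": {"window_size": 1000, "quantile": 0.95},
    "sharing": {"min_carriers": 2, "max_carriers": 100, "min_group": 2},
    "depletion": {"n_genes": 1200, "bin_size": 300, "n_boot": 2000,
                  "planted_sets": {"halved": [120, 0.5]}},
    "segments": {"window_size": 10000},
}


def _merge(base: dict, override: dict, path="") -> dict:
    out = dict(base)
    for key, value in override.items():
        if key not in base:
            raise KeyError(f"unknown config key {path + key!r}")
        if isinstance(base[key], dict) and isinstance(value, dict) \
                and key not in ("groups", "planted_sets"):
            out[key] = _merge(base[key], value, path + key + ".")
        else:
            out[key] = value
    return out


def load_config(path=None, overrides: dict | None = None) -> dict:
    config = DEFAULT_CONFIG
    if path is not None:
        with open(path) as fh:
            config = _merge(config, yaml.safe_load(fh) or {})
    if overrides:
        config = _merge(config, overrides)
    return config


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]


def stage_seeds(seed: int) -> dict[str, int]:
    children = np.random.SeedSequence(seed).spawn(len(STAGES))
    return {name: int(child.generate_state(1)[0] % (2**31))
            for name, child in zip(STAGES, children)}


def run_pipeline(config: dict, out_dir) -> dict:
    """Execute the configured stages in dependency order.

    Returns a manifest dict (also written to ``manifest.json``) mapping
    stage names to their output files and headline numbers.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(int(config["seed"]))
    chash = config_hash(config)
    with open(out / "config.resolved.yaml", "w") as fh:
        yaml.safe_dump({**config, "config_hash": chash}, fh, sort_keys=True)
    manifest: dict = {"config_hash": chash, "stages": {}}
    log: list[str] = []

    def done(stage, **info):
        manifest["stages"][stage] = info
        log.append(f"{stage}: {json.dumps(info, default=str)}")

    enabled = config["stages"]

    table = metadata = None
    if "genotypes" in enabled:
        gconf = simulate.GenotypeConfig(**{
            k: v for k, v in config["genotypes"].items()})
        table, metadata = simulate.simulate_genotype_matrix(
            gconf, seed=seeds["genotypes"])
        vcf_path = out / "genotypes.vcf"
        simulate.write_vcf(table, vcf_path)
        metadata.to_csv(out / "metadata.tsv", sep="\t", index=False)
        done("genotypes", vcf=str(vcf_path), n_sites=len(table.variants),
             n_samples=table.n_samples)

    singleton_sets = []
    if "singletons" in enabled and table is not None:
        reread = variant_io.read_variants(out / "genotypes.vcf")
        for ind in reread.samples:
            ss = variant_io.extract_singletons(reread, ind)
            if len(ss):
                singleton_sets.append(
                    variant_io.nearest_neighbor_distances(ss))
        frames = []
        for ss in singleton_sets:
            df = ss.records.copy()
            df.insert(0, "individual_id", ss.individual_id)
            df["distance"] = ss.distances
            frames.append(df)
        sing = (pd.concat(frames, ignore_index=True) if frames
                else pd.DataFrame())
        sing.to_csv(out / "singletons.tsv", sep="\t", index=False)
        done("singletons", tsv=str(out / "singletons.tsv"), n=len(sing))

    fit = assignment = None
    distances = None
    if "mixture" in enabled:
        mconf = config["mixture"]
        preset = (simulate.PAPERLIKE_PRESET if mconf["preset"] == "paperlike"
                  else mconf["preset"])
        distances, _ = simulate.simulate_mixture_distances(
            preset, n=mconf["n"], seed=seeds["mixture"])
        fit = mixture.select_k(
            distances, alpha=mconf["alpha"], k_max=mconf["k_max"],
            tol=mconf["tol"], max_iter=mconf["max_iter"],
            n_restarts=mconf["restarts"], seed=seeds["mixture"])
        assignment = mixture.classify_singletons(fit, distances)
        with open(out / "mixture_fit.json", "w") as fh:
            json.dump(fit.to_dict(), fh, indent=1)
        done("mixture", json=str(out / "mixture_fit.json"), K=fit.K,
             theta=[round(t, 1) for t in fit.theta])

    if "spectra" in enabled and singleton_sets:
        pooled = pd.concat([s.records for s in singleton_sets],
                           ignore_index=True)
        pooled_d = np.concatenate([
            s.distances[np.isfinite(s.distances)] for s in singleton_sets
        ]) if singleton_sets else np.array([])
        rng = np.random.default_rng(seeds["spectra"])
        comp = rng.integers(1, (fit.K if fit else 2) + 1, size=len(pooled))
        spec = spectra.component_spectra(comp, pooled)
        spec.to_csv(out / "spectra.tsv", sep="\t", index=False)
        done("spectra", tsv=str(out / "spectra.tsv"),
             n_distances_pooled=int(len(pooled_d)))

    if "hotspots" in enabled:
        if singleton_sets and metadata is not None:
            group_of = dict(zip(metadata["individual_id"],
                                metadata["population_group"]))
            pos_frames = []
            for ss in singleton_sets:
                df = ss.records[["chrom", "pos"]].copy()
                df["group"] = group_of.get(ss.individual_id, "all")
                df["component"] = 1
                pos_frames.append(df)
            positions = pd.concat(pos_frames, ignore_index=True)
            chrom_lengths = {
                str(c): int(positions.loc[positions["chrom"] == c,
                                          "pos"].max()) + 1000
                for c in pd.unique(positions["chrom"])
            }
            wtab = hotspots.bin_component_counts(
                positions, chrom_lengths,
                window_size=config["hotspots"]["window_size"])
            flagged = []
            for group in pd.unique(wtab["group"].dropna()):
                flagged.append(hotspots.call_hotspots(
                    wtab, group, 1, config["hotspots"]["quantile"]))
            pd.concat(flagged, ignore_index=True).to_csv(
                out / "window_counts.tsv", sep="\t", index=False)
        wconf = simulate.WindowFeatureConfig()
        wtable = simulate.simulate_window_features(wconf,
                                                   seed=seeds["hotspots"])
        nb = hotspots.fit_nb_regression(
            wtable, "sim", 1, [f"X{m + 1}" for m in range(wconf.n_features)])
        with open(out / "nb_fit.json", "w") as fh:
            json.dump({"beta": nb.beta.to_dict(), "se": nb.se.to_dict(),
                       "dispersion": nb.dispersion, "loglik": nb.loglik,
                       "converged": nb.converged}, fh, indent=1)
        done("hotspots", json=str(out / "nb_fit.json"),
             beta1=round(float(nb.beta.iloc[1]), 3))

    if "sharing" in enabled and table is not None:
        sconf = config["sharing"]
        cm = sharing.build_carrier_matrix(
            table, sconf["min_carriers"], sconf["max_carriers"])
        shared = sharing.group_sharing(cm, metadata,
                                       min_group=sconf["min_group"])
        shared.to_csv(out / "sharing.tsv", sep="\t", index=False)
        done("sharing", tsv=str(out / "sharing.tsv"),
             n_rare=cm.matrix.shape[1])

    if "depletion" in enabled:
        dconf = config["depletion"]
        planted = {k: tuple(v) for k, v in dconf["planted_sets"].items()}
        genes = simulate.simulate_depletion_inputs(
            simulate.DepletionConfig(n_genes=dconf["n_genes"],
                                     planted_sets=planted),
            seed=seeds["depletion"])
        results = []
        for name in planted:
            members = genes.loc[genes[name], "gene_id"]
            res = depletion.length_matched_bootstrap(
                genes, members, set_id=name, n_boot=dconf["n_boot"],
                bin_size=dconf["bin_size"], seed=seeds["depletion"])
            results.append(res.to_dict())
        with open(out / "depletion.json", "w") as fh:
            json.dump(results, fh, indent=1)
        done("depletion", json=str(out / "depletion.json"),
             fold_change_L=[round(r["fold_change_L"], 3) for r in results])

    if "segments" in enabled and table is not None:
        zconf = config["segments"]
        chrom_lengths = {
            str(c): int(table.variants.loc[table.variants["chrom"] == c,
                                           "pos"].max()) + 1000
            for c in pd.unique(table.variants["chrom"])
        }
        coding = {c: np.array([[0, length // 10]])
                  for c, length in chrom_lengths.items()}
        seg = segments.contiguous_segment_counts(
            table, coding, chrom_lengths, window_size=zconf["window_size"])
        seg = segments.adjust_counts(seg) if len(seg) >= 10 else seg
        seg.to_csv(out / "segments.tsv", sep="\t", index=False)
        done("segments", tsv=str(out / "segments.tsv"), n_segments=len(seg))

    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    (out / "run.log").write_text("\n".join(log) + "\n")
    return manifest


def validate_inputs(config: dict, paths: dict | None = None) -> list[str]:
    """Schema and coordinate sanity checks; returns a list of findings."""
    report: list[str] = []
    for key, value in (paths or {}).items():
        p = Path(value)
        if not p.exists():
            report.append(f"{key}: file {p} does not exist")
            continue
        if p.suffix == ".vcf":
            try:
                variant_io.read_variants(p)
            except ValueError as exc:
                report.append(f"{key}: {exc}")
        elif p.suffix == ".bed":
            bed = pd.read_csv(p, sep="\t", header=None, usecols=[0, 1, 2],
                              names=["chrom", "start", "end"], comment="#")
            if (bed["end"] <= bed["start"]).any():
                report.append(
                    f"{key}: intervals with end <= start "
                    "(1-based or malformed BED?)"
                )
    for stage in config.get("stages", []):
        if stage not in STAGES:
            report.append(f"unknown stage {stage!r}")
    return report
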