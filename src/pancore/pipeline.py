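"""End-to-end orchestration: proteomes in, machine-readable report out.

Stages run in the fixed order MGE exclusion -> all-vs-all search -> BBBH ->
clustering -> profile -> partition/fractions/subsets -> trajectories ->
three fits -> openness classification -> (optional) genome distances.
Every stage writes its own artifact into the output directory so any stage
can be re-run or inspected in isolation, and the final ``report.json``
carries every headline number plus the seed and thresholds used.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import io as gio
from .cluster import (
    ClusteringParams,
    all_vs_all_hits,
    best_bidirectional_hits,
    cluster_orthologs,
    exclude_mges,
    strain_map,
    validate_imported_hits,
    write_clusters_tsv,
)
from .distance import distance_matrix, tetra_correlation
from .extrapolate import (
    classify_openness,
    core_trajectory,
    fit_core_decay,
    fit_heaps,
    fit_new_gene_decay,
    leave_one_out_spread,
    new_gene_trajectory,
    pan_trajectory,
)
from .profile import build_profile, core_fraction_per_strain, partition_profile, subset_counts

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    proteome_paths: dict[str, str]  # strain_id -> protein FASTA
    genome_paths: dict[str, str] = field(default_factory=dict)
    similarity_table: str | None = None  # imported hits instead of built-in search
    params: ClusteringParams = field(default_factory=ClusteringParams)
    core_statistic: str = "mean"
    new_gene_statistic: str = "median"
    pan_statistic: str = "median"
    distance_formula: str = "d2"
    outdir: str = "pancore_out"
    seed: int = 0

    def validate(self) -> None:
        if len(self.proteome_paths) < 2:
            raise ValueError("pipeline needs at least 2 strains")
        for strain, path in {**self.proteome_paths, **self.genome_paths}.items():
            if not Path(path).exists():
                raise ValueError(f"strain {strain!r}: path {path} does not exist")
        if self.similarity_table and not Path(self.similarity_table).exists():
            raise ValueError(f"similarity table {self.similarity_table} does not exist")

    @classmethod
    def from_key_value_file(cls, path: str) -> "PipelineConfig":
        """Parse a flat ``key = value`` config file.

        Strain inputs use ``proteome.<strain> = path`` and
        ``genome.<strain> = path`` keys; everything else maps directly onto
        the config fields.
        """
        kv: dict[str, str] = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"{path}: malformed line {line!r}")
            key, value = line.split("=", 1)
            kv[key.strip()] = value.strip()
        proteomes = {
            k.split(".", 1)[1]: v for k, v in kv.items() if k.startswith("proteome.")
        }
        genomes = {
            k.split(".", 1)[1]: v for k, v in kv.items() if k.startswith("genome.")
        }
        cfg = cls(proteome_paths=proteomes, genome_paths=genomes)
        for attr in ("similarity_table", "core_statistic", "new_gene_statistic",
                     "pan_statistic", "distance_formula", "outdir"):
            if attr in kv:
                setattr(cfg, attr, kv[attr])
        if "seed" in kv:
            cfg.seed = int(kv["seed"])
        return cfg


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages and return (and write) the summary report."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    params = config.params
    logger.info(
        "thresholds: BBBH e<=%g id>=%g%%; cluster id>=%g%% len>=%d; MGE keywords %s",
        params.bbbh_e_max, params.bbbh_min_identity, params.cluster_min_identity,
        params.cluster_min_match_length, list(params.mge_keywords),
    )

    stage = "load_proteomes"
    try:
        proteomes = {
            s: gio.read_protein_fasta(p, s)
            for s, p in sorted(config.proteome_paths.items())
        }
        proteome_sizes = {s: len(r) for s, r in proteomes.items()}

        stage = "exclude_mges"
        filtered = {s: exclude_mges(records, params) for s, records in proteomes.items()}

        stage = "similarity_search"
        if config.similarity_table:
            hits = validate_imported_hits(
                gio.read_similarity_table(config.similarity_table), filtered
            )
        else:
            hits = all_vs_all_hits(filtered)

        stage = "clustering"
        pairs = best_bidirectional_hits(hits, params, strain_map(filtered))
        clusters = cluster_orthologs(pairs, hits, params, filtered)
        write_clusters_tsv(clusters, outdir / "clusters.tsv")

        stage = "profile"
        profile = build_profile(clusters, sorted(proteomes), proteome_sizes)
        profile.to_tsv(outdir / "profile.tsv")
        parts = partition_profile(profile)
        fractions, frac_min, frac_max = core_fraction_per_strain(
            parts.core, proteome_sizes
        )
        subsets = subset_counts(profile)

        stage = "trajectories"
        core_traj = core_trajectory(profile)
        new_traj = new_gene_trajectory(profile)
        pan_traj = pan_trajectory(profile)
        _write_trajectories(outdir / "trajectories.tsv", core_traj, new_traj, pan_traj)

        stage = "fits"
        core_fit = fit_core_decay(core_traj, config.core_statistic)
        new_fit = fit_new_gene_decay(new_traj, config.new_gene_statistic)
        heaps_fit = fit_heaps(pan_traj, config.pan_statistic)
        label = classify_openness(heaps_fit.gamma)
        spread = (
            leave_one_out_spread(profile) if profile.n_strains >= 4 else None
        )
        fits = {
            "core_decay": {
                "kappa_c": core_fit.kappa_c, "tau_c": core_fit.tau_c,
                "omega": core_fit.omega, "rss": core_fit.rss,
                "stderr": core_fit.stderr, "unidentifiable": core_fit.unidentifiable,
                "statistic": config.core_statistic,
            },
            "new_gene_decay": {
                "kappa_s": new_fit.kappa_s, "tau_s": new_fit.tau_s,
                "tg_theta": new_fit.tg_theta, "rss": new_fit.rss,
                "stderr": new_fit.stderr, "unidentifiable": new_fit.unidentifiable,
                "statistic": config.new_gene_statistic,
            },
            "heaps": {
                "kappa": heaps_fit.kappa, "gamma": heaps_fit.gamma,
                "rss": heaps_fit.rss, "stderr": heaps_fit.stderr,
                "statistic": config.pan_statistic,
            },
            "openness": label,
            # dispersion across leave-one-strain-out refits; this package's
            # construction of the +/- spreads, not an analytic SE
            "leave_one_out_spread": spread,
        }
        (outdir / "fits.json").write_text(json.dumps(fits, indent=2, sort_keys=True))

        stage = "distances"
        distances = None
        tetra = None
        if len(config.genome_paths) >= 2:
            genomes = {
                s: gio.read_nucleotide_fasta(p)
                for s, p in sorted(config.genome_paths.items())
            }
            dm = distance_matrix(genomes, formula=config.distance_formula)
            dm.to_tsv(outdir / "distances.tsv")
            (outdir / "distances.nwk").write_text(dm.upgma_newick() + "\n")
            distances = {"ids": dm.ids, "values": dm.values.tolist(),
                         "formula": dm.formula}
            ids = dm.ids
            tetra = {
                f"{ids[i]}~{ids[j]}": tetra_correlation(genomes[ids[i]], genomes[ids[j]])
                for i in range(len(ids)) for j in range(i + 1, len(ids))
            }
    except Exception:
        logger.error("pipeline failed at stage %r; partial outputs kept in %s",
                     stage, outdir)
        raise

    report = {
        "seed": config.seed,
        "strains": sorted(proteomes),
        "proteome_sizes": proteome_sizes,
        "n_mge_excluded": {
            s: proteome_sizes[s] - len(filtered[s]) for s in proteome_sizes
        },
        "pan_size": parts.pan,
        "core_size": parts.core,
        "dispensable_size": parts.dispensable,
        "unique_size": parts.unique,
        "per_strain_unique": parts.per_strain_unique,
        "core_fraction_pct": fractions,
        "core_fraction_range": [frac_min, frac_max],
        "subset_counts": {
            "+".join(sorted(k)): v for k, v in subsets.items()
        },
        "fits": fits,
        "distances": distances,
        "tetra_correlation": tetra,
        "thresholds": {
            "bbbh_e_max": params.bbbh_e_max,
            "bbbh_min_identity": params.bbbh_min_identity,
            "cluster_min_identity": params.cluster_min_identity,
            "cluster_min_match_length": params.cluster_min_match_length,
            "mge_keywords": list(params.mge_keywords),
        },
    }
    (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report


def _write_trajectories(path: Path, *trajectories) -> None:
    with open(path, "w") as fh:
        fh.write("curve\tn\tmean\tmedian\tsd\tvalues\n")
        for traj in trajectories:
            means, medians, sds = traj.mean(), traj.median(), traj.std()
            for i, n in enumerate(traj.steps):
                vals = ",".join(f"{v:g}" for v in traj.values[int(n)])
                fh.write(
                    f"{traj.kind}\t{n}\t{means[i]:g}\t{medians[i]:g}\t"
                    f"{sds[i]:g}\t{vals}\n"
                )
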