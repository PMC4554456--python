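"""End-to-end pipeline: simulate -> quantify -> classify -> ordination -> report.

Every stage is a pure function over in-memory records; this module wires
them to files, logging and the run configuration.  Outputs are
deterministic given the seed: rerunning a stage with identical inputs
writes byte-identical tables.
"""

from __future__ import annotations

import hashlib
import itertools
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, io
from .ca import CAResult, fit_ca, plane_summary
from .classify import build_indicator_table, build_phenotype, drop_empty_columns
from .config import PipelineConfig, save_config
from .hosts import HostProfile
from .quantify import (
    NoiseModel,
    PhylogroupProfile,
    QPCRCounts,
    apply_detection_thresholds,
    compute_proportions,
)
from .simulate import simulate_cohort
from .virulence import (
    StrainVFProfile,
    compare_prevalence,
    compare_scores,
    group_prevalence,
    vf_score,
    VF_GENES,
)

logger = logging.getLogger("colitype")


def quantify_counts(
    counts: list[QPCRCounts], noise: NoiseModel
) -> list[tuple[PhylogroupProfile, float]]:
    """Quantify a batch of samples: proportions plus detection flags."""
    out = []
    for rec in counts:
        profile = apply_detection_thresholds(compute_proportions(rec), noise)
        out.append((profile, rec.total_cfu))
    return out


def classify_samples(
    profiles: list[tuple[PhylogroupProfile, float]],
    hosts: list[HostProfile],
    config: PipelineConfig | None = None,
):
    """Phenotype every sample with detectable E. coli; build the animal table.

    Returns ``(phenotypes, host_by_sample, indicator)``; ``indicator`` is
    None when no animal sample has detectable *E. coli* (e.g. an
    all-human cohort, or a cohort with no *E. coli* at all).
    """
    config = config or PipelineConfig()
    host_map = {h.host_id: h for h in hosts}
    phenotypes = []
    pairs = []
    for profile, total in profiles:
        if profile.sample_id not in host_map:
            raise ValueError(f"no host metadata for sample {profile.sample_id!r}")
        if not profile.ecoli_present:
            continue
        host = host_map[profile.sample_id]
        phenotype = build_phenotype(
            profile,
            total,
            host,
            dominant_threshold=config.dominant_threshold,
            intermediate_low=config.intermediate_low,
            exclusivity_threshold=config.exclusivity_threshold,
            cfu_low_bound=config.cfu_low_bound,
            cfu_high_bound=config.cfu_high_bound,
        )
        phenotypes.append(phenotype)
        if not host.is_human:
            pairs.append((phenotype, host))
    indicator = build_indicator_table(pairs, "animal32") if pairs else None
    return phenotypes, host_map, indicator


def ca_coordinates_frame(result: CAResult) -> pd.DataFrame:
    axes = [f"F{k + 1}" for k in range(result.n_axes)]
    rows = pd.DataFrame(result.row_coordinates, columns=axes)
    rows.insert(0, "label", list(result.row_labels))
    rows.insert(0, "kind", "row")
    cols = pd.DataFrame(result.column_coordinates, columns=axes)
    cols.insert(0, "label", list(result.column_labels))
    cols.insert(0, "kind", "column")
    return pd.concat([rows, cols], ignore_index=True)


def ca_summary_frame(result: CAResult) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "axis": [f"F{k + 1}" for k in range(result.n_axes)],
            "singular_value": result.singular_values,
            "principal_inertia": result.principal_inertias,
            "inertia_fraction": result.inertia_fractions,
        }
    )


def vf_report_frame(strains: list[StrainVFProfile]) -> pd.DataFrame:
    """Per-gene prevalence report with pairwise group comparisons.

    One row per gene (prevalence % per group, exact and chi-square
    p-values per group pair, uncorrected) plus summary rows for the mean
    and SD of the virulence score; the score row carries the rank-test
    p-value across groups.
    """
    table = group_prevalence(strains)
    groups = list(table.group_n.index)
    pair_cols = {}
    for a, b in itertools.combinations(groups, 2):
        exact, chi2 = [], []
        for gene in VF_GENES:
            cmp = compare_prevalence(
                (int(table.positive_counts.loc[gene, a]), int(table.group_n[a])),
                (int(table.positive_counts.loc[gene, b]), int(table.group_n[b])),
            )
            exact.append(cmp.exact_p)
            chi2.append(cmp.chi2_p)
        pair_cols[f"exact_p_{a}_vs_{b}"] = exact
        pair_cols[f"chi2_p_{a}_vs_{b}"] = chi2

    frame = pd.DataFrame({"variable": list(VF_GENES)})
    for grp in groups:
        frame[f"{grp}_positive"] = table.positive_counts[grp].to_numpy().astype(int)
        frame[f"{grp}_n"] = int(table.group_n[grp])
        frame[f"{grp}_value"] = (100.0 * table.prevalence[grp]).round(2).to_numpy()
    for name, values in pair_cols.items():
        frame[name] = values

    score_groups = [
        [vf_score(s) for s in strains if s.origin_group == grp] for grp in groups
    ]
    score_p = (
        compare_scores(score_groups).p_value if len(score_groups) >= 2 else float("nan")
    )
    extra = {"variable": ["vf_score_mean", "vf_score_sd"], "score_rank_p": [score_p, None]}
    for grp in groups:
        extra[f"{grp}_n"] = [int(table.group_n[grp])] * 2
        extra[f"{grp}_value"] = [
            round(float(table.mean_score[grp]), 2),
            round(float(table.sd_score[grp]), 2),
        ]
    return pd.concat([frame, pd.DataFrame(extra)], ignore_index=True)


class _WarningCounter(logging.Handler):
    def __init__(self) -> None:
        super().__init__(level=logging.WARNING)
        self.count = 0

    def emit(self, record: logging.LogRecord) -> None:
        self.count += 1


def _config_hash(config: PipelineConfig) -> str:
    import yaml

    text = yaml.safe_dump(config.to_dict(), sort_keys=True)
    return hashlib.sha256(text.encode()).hexdigest()[:12]


def run_pipeline(
    config: PipelineConfig,
    qpcr_path: str | Path | None = None,
    hosts_path: str | Path | None = None,
    strains_path: str | Path | None = None,
) -> dict[str, Path]:
    """Run the full pipeline and write all outputs into ``config.outdir``.

    Without ``qpcr_path``/``hosts_path`` a cohort is simulated from the
    configured templates.  ``strains_path`` defaults to the packaged
    synthetic B2 panel.  Returns the paths written.  A cohort in which no
    sample contains *E. coli* produces empty composition outputs and a
    successful exit.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    log_path = outdir / "run.log"
    file_handler = logging.FileHandler(log_path, mode="w", encoding="utf-8")
    file_handler.setFormatter(
        logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    )
    counter = _WarningCounter()
    logger.addHandler(file_handler)
    logger.addHandler(counter)
    logger.setLevel(logging.INFO)
    try:
        logger.info(
            "colitype %s | seed=%d | config sha256:%s",
            __version__, config.seed, _config_hash(config),
        )
        save_config(config, outdir / "config.yaml")
        written["config"] = outdir / "config.yaml"

        noise = config.noise_model()
        if qpcr_path is None:
            cohort = simulate_cohort(
                list(config.templates), config.n_per_template, noise, config.seed
            )
            hosts = [h for h, _, _ in cohort]
            counts = [q for _, _, q in cohort]
            io.write_qpcr_table(counts, outdir / "qpcr.tsv")
            io.write_metadata(hosts, outdir / "hosts.tsv")
            written["qpcr"] = outdir / "qpcr.tsv"
            written["hosts"] = outdir / "hosts.tsv"
            logger.info("simulated %d samples (%d templates x %d)",
                        len(counts), len(config.templates), config.n_per_template)
        else:
            counts = io.read_qpcr_table(qpcr_path)
            if hosts_path is None:
                raise ValueError("hosts_path is required when qpcr_path is given")
            hosts = io.read_metadata(hosts_path)
            logger.info("read %d qPCR records, %d hosts", len(counts), len(hosts))

        profiles = quantify_counts(counts, noise)
        n_warn = sum(len(p.warnings) for p, _ in profiles)
        io.write_profiles(profiles, outdir / "profiles.tsv")
        written["profiles"] = outdir / "profiles.tsv"
        logger.info(
            "quantified %d samples (%d with E. coli, %d quantification warnings)",
            len(profiles), sum(p.ecoli_present for p, _ in profiles), n_warn,
        )

        phenotypes, _, indicator = classify_samples(profiles, hosts, config)
        io.write_phenotypes(phenotypes, outdir / "phenotypes.tsv")
        written["phenotypes"] = outdir / "phenotypes.tsv"
        if not phenotypes:
            logger.warning(
                "no sample contains detectable E. coli; composition outputs are empty"
            )
        if indicator is not None:
            io.write_indicator(indicator, outdir / "indicator.tsv")
            written["indicator"] = outdir / "indicator.tsv"
            pruned, dropped = drop_empty_columns(indicator)
            if dropped:
                logger.info(
                    "dropped %d unobserved categorie(s) before CA: %s",
                    len(dropped), ", ".join(dropped),
                )
            try:
                result = fit_ca(pruned)
            except ValueError as exc:
                logger.warning("correspondence analysis skipped: %s", exc)
            else:
                ca_coordinates_frame(result).to_csv(
                    outdir / "ca_coordinates.tsv", sep="\t", index=False,
                    lineterminator="\n",
                )
                ca_summary_frame(result).to_csv(
                    outdir / "ca_summary.tsv", sep="\t", index=False,
                    lineterminator="\n",
                )
                written["ca_coordinates"] = outdir / "ca_coordinates.tsv"
                written["ca_summary"] = outdir / "ca_summary.tsv"
                if result.n_axes >= 2:
                    logger.info(
                        "CA: %d axes, F1-F2 inertia fraction %.4f",
                        result.n_axes, plane_summary(result, (1, 2)),
                    )
        else:
            logger.warning(
                "no animal sample with E. coli; indicator table and CA skipped"
            )

        if strains_path is None:
            from .datasets import b2_panel_path

            strains_path = b2_panel_path()
        strains = io.read_strain_table(strains_path)
        report = vf_report_frame(strains)
        report.to_csv(
            outdir / "vf_report.tsv", sep="\t", index=False, lineterminator="\n"
        )
        written["vf_report"] = outdir / "vf_report.tsv"
        logger.info("VF report: %d strains from %s", len(strains), strains_path)

        logger.info("done; %d warning(s) recorded", counter.count)
    finally:
        logger.removeHandler(file_handler)
        logger.removeHandler(counter)
        file_handler.close()
    written["log"] = log_path
    return written
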