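"""End-to-end assembly: synthetic multi-omic data -> inferred TF network.

Glue used by recovery tests, the acceptance checks and the CLI demo: build a
toy genome for a planted ground truth, simulate the expression/ATAC time
course, run differential expression per timepoint, scan regulator motifs in
peaks, assemble pair features, and infer the network under the three
criteria.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from neurotf import expression_stats as es
from neurotf import regulatory_features as rf
from neurotf import synthetic_data as sd
from neurotf.network_inference import CriteriaConfig, TFNetwork, assemble_network


@dataclass
class PipelineResult:
    genome: sd.ToyGenome
    expression: pd.DataFrame
    expr_samples: pd.DataFrame
    atac_counts: pd.DataFrame
    de_tables: Mapping[str, pd.DataFrame]
    hits: pd.DataFrame
    pair_features: pd.DataFrame
    network: TFNetwork


def run_multiomic_pipeline(
    truth: sd.GroundTruth,
    config: sd.SyntheticConfig,
    criteria: CriteriaConfig | None = None,
    motif_p: float = rf.DEFAULT_MOTIF_P,
    **timecourse_kwargs,
) -> PipelineResult:
    """Simulate a planted time course and infer the TF network from it."""
    if criteria is None:
        criteria = CriteriaConfig(baseline=config.timepoints[0],
                                  timepoints=tuple(config.timepoints[1:]))
    genome = sd.generate_toy_genome(truth, config.n_tf, seed=config.seed)
    expression, expr_samples, atac_counts = sd.simulate_timecourse(
        truth, genome, config, **timecourse_kwargs)

    de_tables = es.timepoint_contrasts(
        expression, expr_samples, baseline=criteria.baseline,
        timepoints=list(criteria.timepoints),
        alpha=criteria.alpha, min_fold=criteria.min_fold,
        min_expected=criteria.min_expected_count)

    pwms = [rf.PWM(name=name, matrix=mat) for name, mat in genome.pwms.items()]
    hits = rf.scan_motifs(pwms, genome.peak_sequences(), p=motif_p)
    peak_genes = rf.assign_peaks_to_cres(genome.peaks, genome.genes)
    reads_by_tp = rf.summed_peak_reads(atac_counts, sd.atac_sample_sheet(config))

    regulators = sorted(genome.pwms)
    targets = sd.tf_symbols(config.n_tf)
    pair_features = rf.build_pair_features(hits, peak_genes, reads_by_tp,
                                           regulators, targets)
    network = assemble_network(de_tables, pair_features, criteria,
                               motif_tfs=regulators)
    return PipelineResult(genome=genome, expression=expression,
                          expr_samples=expr_samples, atac_counts=atac_counts,
                          de_tables=de_tables, hits=hits,
                          pair_features=pair_features, network=network)
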