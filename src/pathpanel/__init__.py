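"""pathpanel: design and analysis of counts-based gene-expression panels.

Implements the full workflow around a custom digital counting (nCounter-
style) expression panel: control-based normalization, two-profile pathway
activity scoring, negative-binomial differential expression,
hypergeometric gene-set enrichment, and cohort survival statistics, plus a
synthetic-data generator with known ground truth for end-to-end validation.
"""

from importlib import resources

import pandas as pd

from .panel_core import (
    CountsExperiment,
    Panel,
    PanelFormatError,
    Probe,
    ProbeClass,
    load_counts,
    load_panel,
    write_counts,
    write_panel,
    write_table,
)
from .normalization import control_factors, normalize, normalize_counts
from .activity import fit_reference_profiles, score_activity
from .signature_design import (
    CandidateSeries,
    DesignConfig,
    Signature,
    derive_candidates,
    select_lengths_budget,
)
from .diff_expression import DEResult, bh_adjust, fit_nb_de
from .enrichment import enrich_sets, fisher_right_tail, read_gene_sets
from .cohort_stats import (
    ClinicalTable,
    km_curve,
    logrank_hr,
    median_split,
    summarize_cohort,
)
from .synthetic import (
    GroundTruth,
    SimulationConfig,
    default_ground_truth,
    simulate_cohort,
    simulate_overexpression_experiment,
    simulate_panel,
)

__version__ = "0.1.0"


def load_worked_example_de_table() -> pd.DataFrame:
    """The bundled 57-gene worked-example DE table (MpBC vs TNBC contrast)."""
    with resources.files("pathpanel.data").joinpath(
            "de_worked_example.tsv").open("r", encoding="utf-8") as fh:
        return pd.read_csv(fh, sep="\t", comment="#")
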