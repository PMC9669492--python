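"""rgsc: quantitative repertory-grid self-concept analysis.

Tools for the quantitative arm of repertory-grid studies of self-concept:
standardized Euclidean distances between self elements, opposed-pole-rating
and polarization proportions, clinical questionnaire scoring (PHQ-9, GAD-7,
SWLS, QOLIBRI), Spearman correlation tables with percentile-bootstrap
confidence intervals, and a synthetic cohort generator with known latent
structure for end-to-end validation.
"""

__version__ = "0.1.0"

from .grid import (  # noqa: F401
    IDEAL_SELF,
    PRESENT_SELF,
    SELF_BEFORE_LESION,
    Construct,
    GoatRecord,
    GridElement,
    RatingScale,
    RepertoryGrid,
    goat_eligible,
    read_cohort,
    read_grid_table,
    read_measures_table,
    validate_grid,
    write_cohort,
    write_grid_table,
)
from .indexes import (  # noqa: F401
    ElementPair,
    GridIndexSet,
    all_pairwise_distances,
    compute_indexes,
    element_polarization,
    euclidean_distance,
    indexes_table,
    opposed_pole_proportion,
    total_polarization,
)
from .measures import (  # noqa: F401
    cronbach_alpha,
    score_gad7,
    score_measures,
    score_phq9,
    score_qolibri,
    score_swls,
)
from .pipeline import (  # noqa: F401
    AnalysisConfig,
    StudyReport,
    render_tables,
    run_study,
    run_study_from_paths,
)
from .simulate import (  # noqa: F401
    CohortTruth,
    SimulationConfig,
    simulate_cohort,
    simulate_rank_pairs,
)
from .stats import (  # noqa: F401
    CorrelationCell,
    MeanWithCI,
    bootstrap_ci,
    bootstrap_mean,
    cis_overlap,
    correlate,
    spearman_p,
    spearman_rho,
)


def fixture_cohort_dir():
    """Path to the packaged synthetic example cohort (n=33, fixed seed)."""
    from importlib.resources import files

    return files("rgsc") / "data" / "fixture_cohort"
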