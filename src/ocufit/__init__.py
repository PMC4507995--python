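"""ocufit: fluorescence lifetime analysis for ophthalmic TCSPC data.

Implements the full FLIO/FLIM analysis chain: static and adaptive photon
binning, IRF-convolved decay models (multi-exponential, stretched, spectral
global, layered, lens-corrected, incomplete decay), reduced-chi-square
fitting with variable projection and two-stage minimization, reflection-
artifact and outlier handling, ETDRS-grid region statistics and histogram-
class group comparison — plus a simulator producing synthetic TCSPC cubes
with known ground truth.
"""

from .core import (
    DegenerateDofError,
    DegenerateIRFError,
    FitResultMaps,
    FormatError,
    IRFCurve,
    LensDecay,
    MetadataError,
    OcufitError,
    StudySet,
    SubjectRecord,
    TCSPCCube,
    TimeAxis,
    repetition_period_ns,
)
from .models import (
    ModelSpec,
    ParamVector,
    apply_incomplete_decay,
    evaluate_model,
    evaluate_spectral_global,
    lens_time_shift,
    shift_curve,
)
from .binning import BinningSpec, adaptive_bin, static_bin, sum_all_pixels
from .simulate import (
    GroundTruth,
    expected_curve,
    gaussian_irf,
    sample_histogram,
    simulate_cube,
    simulate_group_study,
    uniform_truth,
)
from .fitting import (
    FitConfig,
    PixelFitResult,
    compute_weights,
    detect_reflection_artifacts,
    fit_image,
    global_init,
    minimize_pixel,
    neighborhood_chi2,
    reduced_chi2,
    solve_amplitudes,
    treat_outliers,
)
from .postprocess import (
    EtdrsGrid,
    RoiStats,
    build_etdrs_grid,
    mean_lifetime,
    roi_histogram,
    roi_statistics,
    spatial_filter,
)
from .groupstats import (
    ClassComparison,
    RocResult,
    compare_groups,
    ranksum_test,
    roc_analysis,
    significance_threshold,
)
from .io import load_cube, load_curve, save_cube, save_results

__version__ = "0.1.0"
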