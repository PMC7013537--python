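"""fallverify: temporal inference models for wearable-altimeter fall verification.

Decides whether a recorded descent incident — the height-time trajectory of
a wearable altimeter dropping from standing height to the floor — is an
involuntary FALL or a voluntary lean-over (BEND).  Two classifiers are
provided: CM-I thresholds the total descent time at the midpoint of the
class mean durations, and CM-II votes per height checkpoint for the nearer
class reference crossing time and decides by majority at floor contact.
"""

__version__ = "0.1.0"

from .incidents import (
    BEND,
    FALL,
    H_FLOOR_TOL,
    CheckpointProfile,
    Incident,
    IncidentError,
    NormalTimeModel,
    checkpoint_grid,
    checkpoint_times,
    total_time,
)
from .simulate import (
    PARAMETER_SETS,
    SimulationConfig,
    duration_models,
    generate_dataset,
    sample_duration,
    simulate_bend,
    simulate_fall,
)
from .classify import (
    CheckpointVoteClassifier,
    StreamVoter,
    TotalTimeThresholdClassifier,
    VoteTrace,
    classify_cm1,
    classify_cm2,
    classify_cm2_stream,
    fit_cm1,
    fit_cm2,
    midpoint_criterion,
)
from .evaluate import (
    ConfusionCounts,
    CVResult,
    McNemarResult,
    accuracy,
    confusion_counts,
    cross_validate,
    mcnemar_test,
    stratified_kfold,
)
from .io import (
    make_fixtures,
    load_model,
    read_incidents,
    save_model,
    write_incidents,
)

__all__ = [
    "__version__",
    "BEND", "FALL", "H_FLOOR_TOL",
    "Incident", "IncidentError", "NormalTimeModel", "CheckpointProfile",
    "total_time", "checkpoint_times", "checkpoint_grid",
    "SimulationConfig", "PARAMETER_SETS", "duration_models",
    "generate_dataset", "sample_duration", "simulate_fall", "simulate_bend",
    "TotalTimeThresholdClassifier", "CheckpointVoteClassifier",
    "StreamVoter", "VoteTrace", "midpoint_criterion",
    "fit_cm1", "classify_cm1", "fit_cm2", "classify_cm2", "classify_cm2_stream",
    "ConfusionCounts", "CVResult", "McNemarResult",
    "accuracy", "confusion_counts", "stratified_kfold", "cross_validate",
    "mcnemar_test",
    "read_incidents", "write_incidents", "save_model", "load_model",
    "make_fixtures",
]
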