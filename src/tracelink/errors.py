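"""Exception and warning types used across the package."""


class TracelinkError(Exception):
    """Base class for all package-specific errors."""


class MissingArea(TracelinkError):
    """An area name referenced by one input is absent from another."""


class ShapeMismatch(TracelinkError):
    """Matrix dimensions are inconsistent with the atlas or each other."""


class ValueOutOfRange(TracelinkError):
    """An entry violates its documented domain (e.g. FLN outside [0, 1])."""


class MissingRegion(TracelinkError):
    """An area has no region assignment."""


class DegenerateDistances(TracelinkError):
    """Distance matrix is identically zero or otherwise unusable."""


class UnknownMethod(TracelinkError):
    """Unrecognised classical-predictor or learner identifier."""


class EmptyTrainingSet(TracelinkError):
    """No injected (training) rows available to compute scores/features."""


class LabelUnavailable(TracelinkError):
    """Ground truth requested for a pair whose target row is unobserved."""


class DegenerateLabels(TracelinkError):
    """Classifier training labels contain a single class."""


class NonFiniteFeature(TracelinkError):
    """A design matrix contains NaN or infinite entries."""


class FeatureLengthMismatch(TracelinkError):
    """Prediction-time feature length differs from the fitted length."""


class BadFoldCount(TracelinkError):
    """Fold count outside 2 <= k <= T."""


class EmptyClass(TracelinkError):
    """A weight-class restriction selects no links."""


class SingleClassLabels(TracelinkError):
    """A class restriction leaves only positives (or only negatives)."""


class BadSubsetSize(TracelinkError):
    """Leave-one-out subset size m outside 2 <= m <= T."""


class BadDimension(TracelinkError):
    """Unsupported geometry dimension."""


class BadT(TracelinkError):
    """Requested number of injections exceeds the number of areas."""


class RewireStall(TracelinkError):
    """Degree-preserving rewiring ran out of admissible swaps."""


class PredictabilityGateFailed(TracelinkError):
    """Imputation refused because cross-validated AUC is near chance."""


class ConfigError(TracelinkError):
    """Invalid or incomplete run configuration."""


class DensityWarning(UserWarning):
    """Binary prediction attempted on an ultra-dense network (few negatives)."""


class LowWeightWarning(UserWarning):
    """FLN below 1e-7 produced a transformed weight below 0."""


class SparseBinWarning(UserWarning):
    """A profile bin holds fewer than the minimum number of points."""
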