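"""Exception hierarchy for data, schema, modeling and persistence errors."""


class QSARKitError(Exception):
    """Base class for all package errors."""


class SchemaConflictError(QSARKitError):
    """Two datasets (or a dataset and a trained model) disagree on a variable
    in a way that cannot be reconciled by type conversion or level reordering."""


class UnfittableFeatureError(QSARKitError):
    """A feature column has no non-missing training values to learn a fill value from."""


class UnsupportedTaskError(QSARKitError):
    """The learner family cannot model the given response (e.g. boosting with
    more than two classes, PLS with a categorical response)."""


class UnsupportedModelError(QSARKitError):
    """The model lacks the bookkeeping an operation needs (e.g. per-tree
    out-of-bag row sets for permutation importance)."""


class InfeasibleFoldsError(QSARKitError):
    """A class has fewer members than the requested number of CV folds."""


class DegenerateResponseError(QSARKitError):
    """The response has zero variance, so no latent direction can be extracted."""


class UncalibratedDomainError(QSARKitError):
    """Applicability-domain assessment requested before quartile calibration."""


class BackendMissingError(QSARKitError):
    """The requested descriptor backend is not available."""


class NoResponseError(QSARKitError):
    """The dataset has no response variable where one is required."""


class NoDataError(QSARKitError):
    """An empty dataset was supplied where examples are required."""


class BundleIntegrityError(QSARKitError):
    """A model bundle is corrupt, truncated or missing required members."""


class BundleVersionError(QSARKitError):
    """A model bundle was written by a newer, unsupported format version."""
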