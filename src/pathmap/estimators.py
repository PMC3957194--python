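"""scikit-learn style estimators over the path-model machinery.

``ModeratedMediation`` fits the three-variable path model at a single
"voxel" (one brain measure); ``VoxelwiseMediation`` sweeps it across a
subjects-by-voxels matrix.  Both follow the sklearn contract:
constructor parameters are hyper-parameters, ``fit`` learns trailing-
underscore attributes, and ``get_params``/``set_params`` come from
``BaseEstimator`` so the classes compose with sklearn model selection.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_array, check_is_fitted

from . import engine
from .bootstrap import BootstrapSettings, bootstrap_indirect, make_resample_plan
from .engine import AnalysisConfig, StatMapSet
from .paths import (
    OLD,
    YOUNG,
    PathVariables,
    conditional_indirect,
    fit_mediator,
    fit_outcome,
)


class ModeratedMediation(BaseEstimator):
    """Moderated-mediation path model for one brain measure.

    Fits B = b0 + a*A + e and C = b0 + b*B + c'*A [+ v*A*B] + e, where
    the columns of X are (group code A, brain measure B) and y is the
    performance measure C.  With ``model='auto'`` the interaction is
    kept only when significant at ``alpha`` (otherwise the model
    degenerates to simple mediation and is refit), mirroring the
    arbitration used voxel-wise.

    Parameters
    ----------
    model : {'auto', 'moderated', 'simple'}
        Which outcome equation to fit; 'auto' arbitrates on the
        interaction p-value.
    alpha : float
        Significance level for arbitration and for the bootstrap CIs.
    n_resamples : int
        Stratified bootstrap resamples; 0 disables the bootstrap.
    ci_method : {'bias_corrected', 'bca', 'percentile'}
    random_state : int
        Seed for the resample plan.

    Attributes
    ----------
    mediator_fit_, outcome_fit_ : fitted equation summaries
    a_, b_, c_prime_, v_ : float path coefficients (v_ is 0.0 for the
        simple model)
    model_kind_ : 'moderated' or 'simple' (the selected model)
    indirect_young_, indirect_old_ : conditional indirect effects
    ci_young_, ci_old_ : IndirectCI bootstrap intervals (when resampled)
    """

    def __init__(self, model: str = "auto", alpha: float = 0.05,
                 n_resamples: int = 5000, ci_method: str = "bias_corrected",
                 random_state: int = 0):
        self.model = model
        self.alpha = alpha
        self.n_resamples = n_resamples
        self.ci_method = ci_method
        self.random_state = random_state

    def fit(self, X, y):
        X = check_array(X)
        y = check_array(y, ensure_2d=False)
        if X.shape[1] != 2:
            raise ValueError("X must have exactly two columns: (group, brain)")
        vars = PathVariables.from_arrays(X[:, 0], X[:, 1], y)

        self.mediator_fit_ = fit_mediator(vars)
        moderated = fit_outcome(vars, "moderated")
        if self.model == "moderated":
            kind = "moderated"
        elif self.model == "simple":
            kind = "simple"
        elif self.model == "auto":
            kind = engine.arbitrate_model(moderated, self.alpha)
            if kind == "degenerate":
                kind = "simple"
        else:
            raise ValueError(f"unknown model {self.model!r}")
        self.outcome_fit_ = moderated if kind == "moderated" else \
            fit_outcome(vars, "simple")
        self.model_kind_ = kind

        self.a_ = self.mediator_fit_.a.estimate
        self.b_ = self.outcome_fit_.b.estimate
        self.c_prime_ = self.outcome_fit_.c_prime.estimate
        self.v_ = self.outcome_fit_.v.estimate if kind == "moderated" else 0.0
        self.intercept_ = self.outcome_fit_.intercept.estimate
        self.indirect_young_ = conditional_indirect(
            self.a_, self.b_, self.v_, YOUNG).value
        self.indirect_old_ = conditional_indirect(
            self.a_, self.b_, self.v_, OLD).value

        if self.n_resamples:
            settings = BootstrapSettings(
                n_resamples=self.n_resamples, alpha=self.alpha,
                ci_method=self.ci_method, seed=self.random_state)
            plan = make_resample_plan(vars.A, settings)
            result = bootstrap_indirect(vars, kind, plan, settings)
            self.ci_young_ = result.young
            self.ci_old_ = result.old
            self.n_dropped_resamples_ = result.n_dropped
        return self

    def predict(self, X):
        """Predicted performance from the fitted outcome equation."""
        check_is_fitted(self, "outcome_fit_")
        X = check_array(X)
        A, B = X[:, 0], X[:, 1]
        return (self.intercept_ + self.b_ * B + self.c_prime_ * A
                + self.v_ * A * B)


class VoxelwiseMediation(BaseEstimator):
    """Voxel-wise moderated-mediation sweep over a data matrix.

    ``fit(X, y, groups=A)`` treats each column of X as one brain
    measure, arbitrates moderated vs simple mediation per column, and
    bootstraps the conditional indirect effects with one shared
    stratified resample plan.  Results land in ``maps_`` (a
    :class:`~pathmap.engine.StatMapSet`); when no mask/affine are given
    the voxels are laid out on a synthetic (V, 1, 1) grid so the same
    reporting path applies.
    """

    def __init__(self, height_alpha: float = 0.05, extent_threshold: int = 50,
                 connectivity: int = 18, n_resamples: int = 5000,
                 ci_method: str = "bias_corrected", random_state: int = 0):
        self.height_alpha = height_alpha
        self.extent_threshold = extent_threshold
        self.connectivity = connectivity
        self.n_resamples = n_resamples
        self.ci_method = ci_method
        self.random_state = random_state

    def _config(self) -> AnalysisConfig:
        return AnalysisConfig(
            height_alpha=self.height_alpha,
            extent_threshold=self.extent_threshold,
            connectivity=self.connectivity,
            bootstrap=BootstrapSettings(
                n_resamples=self.n_resamples, alpha=self.height_alpha,
                ci_method=self.ci_method, seed=self.random_state))

    def fit(self, X, y, groups=None, mask=None, affine=None):
        import pandas as pd

        X = check_array(X)
        y = check_array(y, ensure_2d=False)
        if groups is None:
            raise ValueError("groups (0=young, 1=old per subject) is required")
        groups = np.asarray(groups).ravel()
        n, V = X.shape
        if mask is None:
            mask = np.ones((V, 1, 1), dtype=bool)
        if affine is None:
            affine = np.eye(4)
        ids = tuple(f"sub-{i:04d}" for i in range(n))
        dataset = engine.VoxelDataset(data=X, mask=np.asarray(mask, bool),
                                      affine=np.asarray(affine, float),
                                      subject_ids=ids)
        covariates = pd.DataFrame(
            {"subject_id": ids, "group": groups, "performance": y})
        config = self._config()
        self.maps_: StatMapSet = engine.run_voxelwise(dataset, covariates, config)
        self.moderated_mask_, self.mediation_mask_ = engine.exclusive_partition(
            self.maps_, config)
        self.config_ = config
        return self

    def transform(self, X=None):
        """Per-voxel conditional indirect effects, shape (V, 2)."""
        check_is_fitted(self, "maps_")
        return np.column_stack([self.maps_["ind_young"], self.maps_["ind_old"]])
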