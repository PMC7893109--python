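"""scikit-learn estimator facade over calibration + inference.

``PathwayActivityEstimator`` is a binary classifier in the sklearn sense:
``fit`` calibrates the second layer of the Bayesian pathway model on
ground-truth samples, ``decision_function`` returns the posterior log2 odds
of TF activation, ``predict`` thresholds it at 0, and ``activity_score``
returns the normalized 0-100 score. It composes with sklearn pipelines,
``clone`` and model selection; the module-level functions in
:mod:`pathsig.calibration` and :mod:`pathsig.inference` remain the
lower-level surface it delegates to.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.exceptions import NotFittedError

from .calibration import CalibrationConfig, calibrate
from .io import ACTIVE, INACTIVE, ExpressionMatrix, GroundTruthLabels
from .model import PriorParameters
from .panel import GenePanel

__all__ = ["PathwayActivityEstimator"]


class PathwayActivityEstimator(ClassifierMixin, BaseEstimator):
    """Calibratable pathway-activity classifier.

    Parameters
    ----------
    panel : GenePanel
        Target-gene panel defining the pathway assay.
    priors : PriorParameters or None
        First-layer parameters; defaults to the strong symmetric
        literature-style coupling (0.95 / 0.05, uniform TF prior).
    smoothing_alpha : float
        Laplace pseudo-count for emission fitting.
    min_samples_per_class : int
        Minimum calibration samples per ground-truth class.
    platform_tag : str
        Measurement platform of the training matrix.

    Attributes
    ----------
    model_ : PathwayModel
        The calibrated Bayesian network.
    classes_ : ndarray of shape (2,)
        ``["inactive", "active"]``.

    Notes
    -----
    ``X`` is samples x probes (sklearn orientation): a DataFrame whose
    columns are probe ids, or a plain array whose columns follow
    ``panel.probe_ids`` order. ``y`` holds "active"/"inactive" labels
    (case-insensitive) or 0/1 with 1 = active.
    """

    def __init__(
        self,
        panel: GenePanel | None = None,
        priors: PriorParameters | None = None,
        smoothing_alpha: float = 1.0,
        min_samples_per_class: int = 2,
        platform_tag: str = "intensity",
    ) -> None:
        self.panel = panel
        self.priors = priors
        self.smoothing_alpha = smoothing_alpha
        self.min_samples_per_class = min_samples_per_class
        self.platform_tag = platform_tag

    # -- helpers ----------------------------------------------------------

    def _as_matrix(self, X) -> ExpressionMatrix:
        if isinstance(X, ExpressionMatrix):
            return X
        if isinstance(X, pd.DataFrame):
            df = X.T.copy()
            df.columns = [str(c) for c in df.columns]
        else:
            arr = np.asarray(X, dtype=float)
            if arr.ndim != 2:
                raise ValueError("X must be 2-dimensional (samples x probes)")
            probes = list(self.panel.probe_ids)
            if arr.shape[1] != len(probes):
                raise ValueError(
                    f"X has {arr.shape[1]} columns; panel has "
                    f"{len(probes)} probes"
                )
            df = pd.DataFrame(
                arr.T,
                index=probes,
                columns=[f"s{i}" for i in range(arr.shape[0])],
            )
        return ExpressionMatrix(values=df, platform_tag=self.platform_tag)

    @staticmethod
    def _as_labels(y, sample_ids) -> GroundTruthLabels:
        mapping = {}
        for sid, lab in zip(sample_ids, y):
            if isinstance(lab, str):
                mapping[sid] = lab
            else:
                mapping[sid] = ACTIVE if int(lab) == 1 else INACTIVE
        return GroundTruthLabels(mapping)

    def _check_fitted(self) -> None:
        if not hasattr(self, "model_"):
            raise NotFittedError(
                "This PathwayActivityEstimator is not fitted yet; call "
                "'fit' first."
            )

    # -- sklearn API ------------------------------------------------------

    def fit(self, X, y) -> "PathwayActivityEstimator":
        """Calibrate thresholds and emission parameters on labeled samples."""
        if self.panel is None:
            raise ValueError("a GenePanel is required to fit")
        matrix = self._as_matrix(X)
        labels = (
            y
            if isinstance(y, GroundTruthLabels)
            else self._as_labels(y, matrix.samples)
        )
        config = CalibrationConfig(
            smoothing_alpha=self.smoothing_alpha,
            min_samples_per_class=self.min_samples_per_class,
        )
        self.model_ = calibrate(
            self.panel,
            matrix,
            labels,
            priors=self.priors,
            config=config,
            platform_tag=matrix.platform_tag,
        )
        self.classes_ = np.array([INACTIVE, ACTIVE])
        self.n_features_in_ = len(self.panel.probe_ids)
        return self

    def decision_function(self, X) -> np.ndarray:
        """Posterior log2 odds of TF activation, one value per sample."""
        from .inference import infer  # deferred to avoid import cycle at init

        self._check_fitted()
        matrix = self._as_matrix(X)
        return np.array(
            [
                infer(self.model_, matrix.sample(sid), sample_id=sid).log2_odds
                for sid in matrix.samples
            ]
        )

    def predict(self, X) -> np.ndarray:
        """Label "active" where the posterior log2 odds is positive."""
        L = self.decision_function(X)
        return np.where(L > 0, ACTIVE, INACTIVE)

    def predict_proba(self, X) -> np.ndarray:
        """Posterior P(inactive), P(active) per sample from the log2 odds."""
        L = self.decision_function(X)
        p_active = 1.0 / (1.0 + np.exp2(-L))
        return np.column_stack([1.0 - p_active, p_active])

    def activity_score(self, X) -> np.ndarray:
        """Normalized 0-100 pathway activity score per sample."""
        from .inference import infer

        self._check_fitted()
        matrix = self._as_matrix(X)
        return np.array(
            [
                infer(self.model_, matrix.sample(sid), sample_id=sid).score
                for sid in matrix.samples
            ]
        )
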