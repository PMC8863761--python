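"""Model/Results facade over the factoring pipeline.

:class:`ExploratoryFactorModel` is constructed from raw data or a
correlation matrix; ``fit`` runs principal axis factoring followed by
varimax and promax rotation under a preset or explicit settings and
returns an :class:`EFAResults` carrying loadings, pattern, structure,
factor intercorrelations, communalities, convergence diagnostics, and a
``summary()`` table.
"""

from __future__ import annotations

import json
from dataclasses import asdict

import numpy as np
import pandas as pd

from .corrprep import CorrelationMatrix, correlation_from_raw, smooth_to_pd
from .evaluate import heywood_check, is_admissible
from .paf import PAFSettings, UnrotatedSolution, paf_extract_with_fallback
from .popsim import ImplementationSpec, get_spec
from .rotate import RotatedSolution, RotationSettings, rotate


class ExploratoryFactorModel:
    """Exploratory factor analysis by iterative principal axis factoring.

    Parameters
    ----------
    corr
        The indicator intercorrelation matrix to factor.
    nobs
        Sample size behind ``corr``, when known (kept as metadata).
    """

    def __init__(self, corr: CorrelationMatrix, nobs: int | None = None):
        if not isinstance(corr, CorrelationMatrix):
            corr = CorrelationMatrix(np.asarray(corr, dtype=float))
        self.corr = corr
        self.nobs = nobs

    # ------------------------------------------------------------ builders

    @classmethod
    def from_raw(cls, data, indicator_names=None) -> "ExploratoryFactorModel":
        data = np.asarray(data, dtype=float)
        return cls(correlation_from_raw(data, indicator_names), nobs=data.shape[0])

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ExploratoryFactorModel":
        return cls(correlation_from_raw(df), nobs=len(df))

    @classmethod
    def from_csv(cls, path) -> "ExploratoryFactorModel":
        """Load either a square correlation CSV or a rectangular raw-data CSV."""
        df = pd.read_csv(path, index_col=0)
        square = df.shape[0] == df.shape[1] and list(df.index) == list(df.columns)
        if square:
            return cls(CorrelationMatrix.from_csv(path))
        # raw data: first column may be an observation id; re-read plainly
        df = pd.read_csv(path)
        return cls.from_dataframe(df)

    @property
    def indicator_names(self):
        return self.corr.indicator_names

    # ----------------------------------------------------------------- fit

    def fit(
        self,
        n_factors: int,
        preset: str | ImplementationSpec | None = None,
        paf_settings: PAFSettings | None = None,
        rotation_settings: RotationSettings | None = None,
        nonpd: str | None = None,
    ) -> "EFAResults":
        """Run PAF + varimax + promax and return the results object.

        Either name a preset (``psych_smc``, ``psych_unity``, ``spss``,
        ``best``) or pass explicit settings objects; explicit objects
        override the corresponding preset component.
        """
        if preset is not None:
            spec = get_spec(preset)
            paf_settings = paf_settings or spec.paf
            rotation_settings = rotation_settings or spec.rot
            nonpd = nonpd or spec.nonpd
        paf_settings = paf_settings or PAFSettings()
        rotation_settings = rotation_settings or RotationSettings()
        nonpd = nonpd or "smooth"
        R = smooth_to_pd(self.corr, mode=nonpd)
        smoothed = R is not self.corr
        unrotated = paf_extract_with_fallback(R, n_factors, paf_settings)
        rotated = rotate(unrotated.loadings, rotation_settings)
        return EFAResults(self, unrotated, rotated, smoothed=smoothed)


class EFAResults:
    """Fitted factor solution with diagnostics.

    Attributes
    ----------
    unrotated, rotated
        The stage results (:class:`UnrotatedSolution`,
        :class:`RotatedSolution`).
    smoothed
        Whether the input correlation matrix required smoothing.
    """

    def __init__(
        self,
        model: ExploratoryFactorModel,
        unrotated: UnrotatedSolution,
        rotated: RotatedSolution,
        smoothed: bool = False,
    ):
        self.model = model
        self.unrotated = unrotated
        self.rotated = rotated
        self.smoothed = smoothed

    # convenient views ----------------------------------------------------

    @property
    def loadings(self) -> np.ndarray:
        return self.unrotated.loadings

    @property
    def varimax_loadings(self) -> np.ndarray:
        return self.rotated.varimax_loadings

    @property
    def pattern(self) -> np.ndarray:
        return self.rotated.pattern

    @property
    def structure(self) -> np.ndarray:
        return self.rotated.structure

    @property
    def phi(self) -> np.ndarray:
        return self.rotated.phi

    @property
    def communalities(self) -> np.ndarray:
        return self.unrotated.communalities

    @property
    def converged(self) -> bool:
        return self.unrotated.converged

    @property
    def n_factors(self) -> int:
        return self.unrotated.m

    @property
    def heywood(self) -> bool:
        return heywood_check(self.unrotated)

    @property
    def admissible(self) -> bool:
        return is_admissible(self.rotated, self.unrotated)

    # presentation --------------------------------------------------------

    def _factor_cols(self):
        return [f"F{j + 1}" for j in range(self.n_factors)]

    def pattern_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.pattern, index=self.model.indicator_names, columns=self._factor_cols()
        )

    def summary(self) -> str:
        """Plain-text summary: settings, convergence, pattern, phi, communalities."""
        s = self.unrotated.settings_used
        r = self.rotated.settings_used
        lines = [
            "Exploratory Factor Analysis (principal axis factoring + promax)",
            "=" * 66,
            f"indicators: {self.unrotated.p}    factors: {self.n_factors}"
            + (f"    nobs: {self.model.nobs}" if self.model.nobs else ""),
            f"PAF: init={s.init_comm}, abs_eigen={s.abs_eigen}, "
            f"criterion={s.criterion:g} ({s.criterion_type})",
            f"rotation: varimax={r.varimax_type}, kaiser_normalize={r.kaiser_normalize}, "
            f"target={r.p_type}, k={r.k}",
            f"converged: {self.converged} in {self.unrotated.iterations} iterations"
            + ("  [smoothed input]" if self.smoothed else "")
            + (
                f"  [fallback: {self.unrotated.fallback_used}]"
                if self.unrotated.fallback_used
                else ""
            ),
            f"Heywood case: {self.heywood}    admissible: {self.admissible}",
            "",
            "Promax pattern coefficients",
            self.pattern_frame().round(4).to_string(),
            "",
            "Factor intercorrelations (phi)",
            pd.DataFrame(
                self.phi, index=self._factor_cols(), columns=self._factor_cols()
            )
            .round(4)
            .to_string(),
            "",
            "Communalities",
            pd.Series(self.communalities, index=self.model.indicator_names)
            .round(4)
            .to_string(),
        ]
        return "\n".join(lines)

    # serialization -------------------------------------------------------

    def to_dict(self) -> dict:
        """Full solution bundle with every resolved setting (no hidden defaults)."""
        return {
            "settings": {
                "paf": asdict(self.unrotated.settings_used),
                "rotation": asdict(self.rotated.settings_used),
            },
            "indicator_names": list(self.model.indicator_names),
            "n_factors": self.n_factors,
            "converged": self.converged,
            "iterations": self.unrotated.iterations,
            "smoothed": self.smoothed,
            "fallback_used": self.unrotated.fallback_used,
            "heywood": self.heywood,
            "admissible": self.admissible,
            "initial_communalities": self.unrotated.initial_communalities.tolist(),
            "communalities": self.communalities.tolist(),
            "unrotated_loadings": self.loadings.tolist(),
            "varimax_loadings": self.varimax_loadings.tolist(),
            "pattern": self.pattern.tolist(),
            "structure": self.structure.tolist(),
            "phi": self.phi.tolist(),
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    def to_csv(self, prefix) -> list[str]:
        """Write pattern/structure/loadings/phi/communalities CSVs; return the paths."""
        cols = self._factor_cols()
        names = self.model.indicator_names
        written = []
        for tag, mat in [
            ("unrotated", self.loadings),
            ("varimax", self.varimax_loadings),
            ("pattern", self.pattern),
            ("structure", self.structure),
        ]:
            path = f"{prefix}_{tag}.csv"
            pd.DataFrame(mat, index=names, columns=cols).to_csv(path, float_format="%.10g")
            written.append(path)
        path = f"{prefix}_phi.csv"
        pd.DataFrame(self.phi, index=cols, columns=cols).to_csv(path, float_format="%.10g")
        written.append(path)
        path = f"{prefix}_communalities.csv"
        pd.Series(self.communalities, index=names, name="communality").to_csv(
            path, float_format="%.10g"
        )
        written.append(path)
        return written
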