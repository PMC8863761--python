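"""Population models, implementation grid, and the factor-recovery simulation.

A population model is a pattern matrix Lambda and a factor intercorrelation
matrix Phi. Its implied population correlation matrix is

    R = Lambda Phi Lambda',  diag(R) = 1,

from which multivariate-normal samples are drawn (means 0, SDs 1, so the
covariance equals R). Pattern matrices are written in a compact code
``p|m|lambda[|c]``: p indicators, m factors, the set of unique non-zero
pattern coefficients as digits (6 -> .6; 46 -> {.4, .6}), an optional
``wb`` suffix for loadings mixed within and between factors, and an
optional fourth field ``Nc`` for N cross-loadings. Example: ``18|3|46|3c``.

The implementation grid crosses every PAF setting with every rotation
setting that differs between programs; the default levels give exactly
192 implementations, containing the presets that emulate the R psych and
SPSS pipelines and the recommended "best" combination.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from itertools import product

import numpy as np
import pandas as pd
import yaml

from .corrprep import CorrelationMatrix, correlation_from_raw, smooth_to_pd
from .evaluate import correspondence_diff, heywood_check, rmse, salient_map, align_factors
from .exceptions import (
    DegenerateInputError,
    NegativeEigenvalueError,
    NotPositiveDefiniteError,
    ParseError,
)
from .paf import PAFSettings, paf_extract_with_fallback
from .rotate import RotationSettings, rotate

_CODE_RE = re.compile(r"^(\d+)\|(\d+)\|([1-9]+)(wb)?(?:\|(\d+)c)?$")

#: default factor-intercorrelation levels: orthogonal, moderate, high, mixed
DEFAULT_PHI_LEVELS: tuple = (0.0, 0.3, 0.7, "mixed")

#: values cycled over factor pairs for the "mixed" intercorrelation level
MIXED_PHI_VALUES = (0.3, 0.5, 0.7)


# --------------------------------------------------------------------------
# population models
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class CodeSkeleton:
    """Parsed form of a ``p|m|lambda[|c]`` pattern code."""

    p: int
    m: int
    loadings: tuple[float, ...]
    within_between: bool
    n_cross: int
    code: str


def parse_code(code: str) -> CodeSkeleton:
    """Parse a pattern-matrix code; see the module docstring for the grammar."""
    match = _CODE_RE.match(code.strip())
    if match is None:
        raise ParseError(f"cannot parse population-model code {code!r}")
    p = int(match.group(1))
    m = int(match.group(2))
    digits = match.group(3)
    loadings = tuple(int(d) / 10.0 for d in digits)
    wb = match.group(4) is not None
    n_cross = int(match.group(5)) if match.group(5) else 0
    if p < 2 or m < 1:
        raise ParseError(f"code {code!r}: need p >= 2 and m >= 1")
    if len(set(loadings)) != len(loadings):
        raise ParseError(f"code {code!r}: repeated loading digit")
    if wb and len(loadings) == 1:
        raise ParseError(f"code {code!r}: 'wb' requires more than one loading value")
    if n_cross > p:
        raise ParseError(f"code {code!r}: more cross-loadings than indicators")
    return CodeSkeleton(p=p, m=m, loadings=loadings, within_between=wb, n_cross=n_cross, code=code)


def build_pattern(skeleton: CodeSkeleton) -> np.ndarray:
    """Construct the p x m pattern matrix a code describes.

    Indicators are split into m equal blocks of p/m, one block per factor.
    A single loading value fills every primary loading; several values are
    cycled per *factor* by default and per *indicator within each factor*
    under the ``wb`` flag. Cross-loadings give the first ``n_cross``
    indicators a secondary loading (the smallest value in the set) on the
    next factor, cyclically.
    """
    p, m = skeleton.p, skeleton.m
    if p % m != 0:
        raise ValueError(f"code {skeleton.code!r}: p={p} is not divisible by m={m}")
    per = p // m
    Lam = np.zeros((p, m))
    vals = skeleton.loadings
    for f in range(m):
        for i in range(per):
            row = f * per + i
            if skeleton.within_between:
                # factor-indexed offset mixes the values both within and
                # between factors, and keeps every value in use even when
                # p/m is smaller than the number of values
                Lam[row, f] = vals[(i + f) % len(vals)]
            else:
                Lam[row, f] = vals[f % len(vals)]
    cross_val = min(vals)
    for row in range(skeleton.n_cross):
        own = row // per
        Lam[row, (own + 1) % m] = cross_val
    return Lam


def make_phi(m: int, spec) -> np.ndarray:
    """Factor intercorrelation matrix for a level specification.

    ``spec`` is a scalar (constant off-diagonal), the string ``"mixed"``
    (cycle .3/.5/.7 over the factor pairs), or an explicit m x m matrix.
    """
    if isinstance(spec, str):
        if spec != "mixed":
            raise ValueError(f"unknown phi level {spec!r}")
        Phi = np.eye(m)
        k = 0
        for i in range(m):
            for j in range(i + 1, m):
                Phi[i, j] = Phi[j, i] = MIXED_PHI_VALUES[k % len(MIXED_PHI_VALUES)]
                k += 1
    elif np.isscalar(spec):
        Phi = np.full((m, m), float(spec))
        np.fill_diagonal(Phi, 1.0)
    else:
        Phi = np.asarray(spec, dtype=float)
        if Phi.shape != (m, m):
            raise ValueError(f"phi matrix must be {m}x{m}")
    if np.linalg.eigvalsh(Phi)[0] < -1e-10:
        raise ValueError("factor intercorrelation matrix is not positive semidefinite")
    return Phi


def _phi_label(spec) -> str:
    if isinstance(spec, str):
        return spec
    if np.isscalar(spec):
        return f"{float(spec):g}"
    return "custom"


@dataclass(frozen=True)
class PopulationModel:
    """Ground-truth factor model: pattern matrix, Phi, and its code."""

    code: str
    Lambda: np.ndarray
    Phi: np.ndarray
    phi_label: str = "custom"

    def __post_init__(self):
        Lam = np.asarray(self.Lambda, dtype=float)
        Phi = np.asarray(self.Phi, dtype=float)
        if Phi.shape != (Lam.shape[1], Lam.shape[1]):
            raise ValueError("Phi order must equal the number of factors")
        Lam.flags.writeable = False
        Phi.flags.writeable = False
        object.__setattr__(self, "Lambda", Lam)
        object.__setattr__(self, "Phi", Phi)

    @classmethod
    def from_code(cls, code: str, phi=0.0) -> "PopulationModel":
        skel = parse_code(code)
        return cls(
            code=skel.code,
            Lambda=build_pattern(skel),
            Phi=make_phi(skel.m, phi),
            phi_label=_phi_label(phi),
        )

    @property
    def p(self) -> int:
        return self.Lambda.shape[0]

    @property
    def m(self) -> int:
        return self.Lambda.shape[1]

    @property
    def loading_set(self) -> frozenset:
        return frozenset(np.round(self.Lambda[self.Lambda != 0], 10))

    @property
    def n_cross(self) -> int:
        return int(np.sum(np.sum(self.Lambda != 0, axis=1) > 1))

    @property
    def label(self) -> str:
        return f"{self.code}~phi={self.phi_label}"

    def correlation(self) -> CorrelationMatrix:
        return population_correlation(self)

    def sample(self, n: int, seed=None) -> np.ndarray:
        return sample_data(self.correlation(), n, seed)


def population_correlation(model: PopulationModel) -> CorrelationMatrix:
    """Implied population correlation matrix R = Lambda Phi Lambda', diag 1."""
    R = model.Lambda @ model.Phi @ model.Lambda.T
    off = R[~np.eye(model.p, dtype=bool)]
    if off.size and np.max(np.abs(off)) > 1.0 + 1e-12:
        raise ValueError(
            f"model {model.code!r} implies correlations outside [-1, 1]; invalid model"
        )
    np.fill_diagonal(R, 1.0)
    return CorrelationMatrix(R)


def sample_data(R: CorrelationMatrix, n: int, seed=None) -> np.ndarray:
    """Draw an n x p multivariate-normal sample with covariance R.

    Uses the Cholesky factor of R, falling back to an eigendecomposition
    square root when R is positive semidefinite but singular.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    vals = R.values
    try:
        L = np.linalg.cholesky(vals)
    except np.linalg.LinAlgError:
        w, V = np.linalg.eigh(vals)
        if w[0] < -1e-8:
            raise NotPositiveDefiniteError(
                "correlation matrix is indefinite; smooth it before sampling"
            ) from None
        L = V * np.sqrt(np.maximum(w, 0.0))
    z = rng.standard_normal((n, R.p))
    return z @ L.T


# --------------------------------------------------------------------------
# implementation grid
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ImplementationSpec:
    """One point in the settings grid: a PAF configuration plus a rotation one."""

    paf: PAFSettings
    rot: RotationSettings
    label: str
    nonpd: str = "smooth"  # how non-positive-definite input is handled

    def settings_key(self) -> tuple:
        """Grid identity: the settings actually varied across implementations."""
        return (
            self.paf.init_comm,
            self.paf.abs_eigen,
            self.paf.criterion_type,
            self.paf.criterion,
            self.rot.varimax_type,
            self.rot.p_type,
            self.rot.k,
        )


DEFAULT_GRID_LEVELS: dict = {
    "init_comm": ("unity", "mac", "smc"),
    "abs_eigen": (True, False),
    "criterion_type": ("sum", "max_individual"),
    "criterion": (1e-3, 1e-6),
    "varimax_type": ("kaiser", "svd"),
    "p_type": ("unnorm", "norm"),
    "k_rule": ("always4", "tataryn"),  # tataryn: k=3 unnorm / k=2 norm
}


def _k_for(rule: str, p_type: str) -> int:
    if rule == "always4":
        return 4
    if rule == "tataryn":
        return 3 if p_type == "unnorm" else 2
    raise ValueError(f"unknown k rule {rule!r}")


def enumerate_grid(config: dict | None = None) -> list[ImplementationSpec]:
    """Cartesian product of the varied settings levels (default: 192 specs)."""
    levels = dict(DEFAULT_GRID_LEVELS)
    if config:
        unknown = set(config) - set(levels)
        if unknown:
            raise ValueError(f"unknown grid dimensions: {sorted(unknown)}")
        levels.update(config)
    specs = []
    seen = set()
    for init, abse, ctype, crit, vtype, ptype, krule in product(
        levels["init_comm"],
        levels["abs_eigen"],
        levels["criterion_type"],
        levels["criterion"],
        levels["varimax_type"],
        levels["p_type"],
        levels["k_rule"],
    ):
        k = _k_for(krule, ptype)
        label = (
            f"{init}_{'abs' if abse else 'raw'}_{ctype}_{crit:.0e}"
            f"_{vtype}_{ptype}_k{k}"
        )
        if label in seen:
            raise ValueError(f"duplicate implementation label {label!r}")
        seen.add(label)
        specs.append(
            ImplementationSpec(
                paf=PAFSettings(
                    init_comm=init,
                    abs_eigen=abse,
                    criterion_type=ctype,
                    criterion=crit,
                    smc_fail_fallback="error",
                ),
                rot=RotationSettings(varimax_type=vtype, p_type=ptype, k=k),
                label=label,
            )
        )
    return specs


def _preset(name, init, abse, ctype, vtype, ptype, k, fallback, nonpd) -> ImplementationSpec:
    return ImplementationSpec(
        paf=PAFSettings(
            init_comm=init,
            abs_eigen=abse,
            criterion_type=ctype,
            criterion=1e-3,
            smc_fail_fallback=fallback,
        ),
        rot=RotationSettings(varimax_type=vtype, p_type=ptype, k=k),
        label=name,
        nonpd=nonpd,
    )


#: named implementations: the two program emulations and the recommended mix
PRESETS: dict[str, ImplementationSpec] = {
    # R psych pipeline: SMC seeds, raw eigenvalues, sum referent, SVD varimax,
    # unnormalized promax target; smooths non-PD input; falls back to unity
    # seeds when SMCs fail.
    "psych_smc": _preset("psych_smc", "smc", False, "sum", "svd", "unnorm", 4, "unity", "smooth"),
    # same pipeline started from unity seeds
    "psych_unity": _preset("psych_unity", "unity", False, "sum", "svd", "unnorm", 4, "error", "smooth"),
    # SPSS pipeline: SMC seeds, absolute eigenvalues, max-individual referent,
    # classic varimax, row-normalized promax target; aborts on non-PD input;
    # MAC seeds when SMCs fail.
    "spss": _preset("spss", "smc", True, "max_individual", "kaiser", "norm", 4, "mac", "abort"),
    # recommended combination: SMC seeds, absolute eigenvalues, sum referent,
    # 1e-3 tolerance, classic varimax with a row-normalized target, k = 4
    "best": _preset("best", "smc", True, "sum", "kaiser", "norm", 4, "unity", "smooth"),
}


def get_spec(preset_or_spec) -> ImplementationSpec:
    if isinstance(preset_or_spec, ImplementationSpec):
        return preset_or_spec
    try:
        return PRESETS[preset_or_spec]
    except KeyError:
        raise ValueError(
            f"unknown preset {preset_or_spec!r}; choose from {sorted(PRESETS)}"
        ) from None


# --------------------------------------------------------------------------
# default study manifest
# --------------------------------------------------------------------------

#: 27 pattern-matrix codes spanning 3- and 6-factor designs, indicator-to-
#: factor ratios from 2 to 6, weak/strong/heterogeneous loadings, and
#: cross-loading variants
DEFAULT_PATTERN_CODES: tuple[str, ...] = (
    # m = 3, homogeneous loadings
    "6|3|3", "6|3|6", "6|3|9",
    "12|3|3", "12|3|6", "12|3|9",
    "18|3|3", "18|3|6", "18|3|9",
    # m = 3, heterogeneous loadings (between factors, and within/between)
    "6|3|46", "12|3|46", "18|3|46",
    "6|3|369wb", "12|3|369wb", "18|3|369wb",
    # m = 3, cross-loading variants
    "12|3|46|3c", "18|3|6|3c", "18|3|46|3c",
    # m = 6
    "12|6|3", "18|6|3", "24|6|3",
    "12|6|6", "18|6|6", "24|6|6",
    "12|6|369wb", "18|6|369wb", "24|6|369wb",
)


def default_manifest() -> list[PopulationModel]:
    """The default study design: 27 pattern codes x 4 Phi levels = 108 models."""
    return [
        PopulationModel.from_code(code, phi)
        for code in DEFAULT_PATTERN_CODES
        for phi in DEFAULT_PHI_LEVELS
    ]


def load_manifest(path) -> list[PopulationModel]:
    """Load a YAML manifest: ``codes: [...]`` and ``phi_levels: [...]``.

    Phi levels may be numbers or the string ``mixed``. An omitted key falls
    back to the default codes / levels.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    codes = doc.get("codes", list(DEFAULT_PATTERN_CODES))
    phis = doc.get("phi_levels", list(DEFAULT_PHI_LEVELS))
    return [PopulationModel.from_code(str(c), phi) for c in codes for phi in phis]


# --------------------------------------------------------------------------
# simulation runner
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class SimulationRecord:
    """Outcome of one implementation on one simulated data set."""

    model_code: str
    phi_label: str
    n: int
    replicate: int
    seed: int
    implementation_label: str
    rmse: float
    heywood: bool
    correspondence_errors: int
    negative_eigenvalue_encountered: bool
    converged: bool
    failed: bool = False


def _record_seed(master_seed: int, model_idx: int, n: int, replicate: int) -> int:
    """Deterministic per-data-set seed; subsets of the design re-run identically."""
    ss = np.random.SeedSequence([int(master_seed), int(model_idx), int(n), int(replicate)])
    return int(ss.generate_state(1)[0] % (2**31))


def analyze_sample(
    data: np.ndarray, model: PopulationModel, spec: ImplementationSpec
) -> dict:
    """Fit one implementation to one sample and score it against the truth."""
    out = {
        "rmse": np.nan,
        "heywood": False,
        "correspondence_errors": -1,
        "negative_eigenvalue_encountered": False,
        "converged": False,
        "failed": True,
    }
    try:
        R = correlation_from_raw(data)
        R = smooth_to_pd(R, mode=spec.nonpd)
    except (DegenerateInputError, NotPositiveDefiniteError):
        return out
    try:
        paf_sol = paf_extract_with_fallback(R, model.m, spec.paf)
    except NegativeEigenvalueError:
        out["negative_eigenvalue_encountered"] = True
        return out
    if paf_sol.fallback_used is not None:
        out["negative_eigenvalue_encountered"] = True
    rot_sol = rotate(paf_sol.loadings, spec.rot)
    alignment = align_factors(rot_sol.pattern, model.Lambda)
    aligned = alignment.apply(rot_sol.pattern)
    out["rmse"] = rmse(model.Lambda, aligned, align=False)
    out["heywood"] = heywood_check(paf_sol)
    out["correspondence_errors"] = correspondence_diff(
        salient_map(model.Lambda), salient_map(aligned)
    )
    out["converged"] = paf_sol.converged
    out["failed"] = False
    return out


def run_simulation(
    models,
    n_values,
    reps: int,
    specs,
    seed: int = 0,
    progress=None,
) -> list[SimulationRecord]:
    """Factor-recovery simulation over models x sample sizes x replicates x specs.

    Each (model, n, replicate) cell draws one data set, shared across all
    implementations, from a seed derived deterministically from the master
    seed. Failures of individual runs are recorded, never raised.
    """
    if reps < 1:
        raise ValueError("reps must be at least 1")
    models = list(models)
    specs = list(specs)
    records: list[SimulationRecord] = []
    for model_idx, model in enumerate(models):
        R = model.correlation()
        for n in n_values:
            for rep in range(reps):
                s = _record_seed(seed, model_idx, n, rep)
                data = sample_data(R, int(n), np.random.default_rng(s))
                for spec in specs:
                    res = analyze_sample(data, model, spec)
                    records.append(
                        SimulationRecord(
                            model_code=model.code,
                            phi_label=model.phi_label,
                            n=int(n),
                            replicate=rep,
                            seed=s,
                            implementation_label=spec.label,
                            rmse=res["rmse"],
                            heywood=res["heywood"],
                            correspondence_errors=res["correspondence_errors"],
                            negative_eigenvalue_encountered=res[
                                "negative_eigenvalue_encountered"
                            ],
                            converged=res["converged"],
                            failed=res["failed"],
                        )
                    )
                if progress is not None:
                    progress(model, n, rep)
    return records


def records_to_frame(records) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])


def aggregate(records) -> pd.DataFrame:
    """Per model x n x implementation summary, ordered best to worst.

    Columns: mean RMSE (MRMSE, over non-failed runs), proportion of Heywood
    cases, proportion of solutions with at least one incorrect
    indicator-to-factor correspondence, and the failure proportion. Ties in
    MRMSE order alphabetically by implementation label.
    """
    df = records_to_frame(list(records))
    if df.empty:
        raise ValueError("no records to aggregate")
    ok = df[~df["failed"]]
    grouped = df.groupby(["model_code", "phi_label", "n", "implementation_label"])
    out = grouped.agg(n_runs=("rmse", "size"), failed_prop=("failed", "mean"))
    ok_grouped = ok.groupby(["model_code", "phi_label", "n", "implementation_label"])
    out["mrmse"] = ok_grouped["rmse"].mean()
    out["heywood_prop"] = ok_grouped["heywood"].mean()
    out["correspondence_error_prop"] = ok_grouped["correspondence_errors"].apply(
        lambda s: float(np.mean(s > 0))
    )
    out["mean_correspondence_errors"] = ok_grouped["correspondence_errors"].mean()
    out = out.reset_index()
    return out.sort_values(
        ["model_code", "phi_label", "n", "mrmse", "implementation_label"],
        kind="mergesort",
    ).reset_index(drop=True)


def design_size(n_models: int = 108, n_sample_sizes: int = 2, reps: int = 1000) -> int:
    """Number of simulated data sets the full design specifies."""
    return n_models * n_sample_sizes * reps
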