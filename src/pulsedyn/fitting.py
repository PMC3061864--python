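"""Variable-projection global fitting of time-resolved data.

The model is bilinear: nonlinear kinetic parameters (rate constants, and
optionally IRF centre/width) are shared by every detection channel, while each
channel's amplitudes (the species/decay-associated spectra) and baseline
offset enter linearly.  At every evaluation of the nonlinear objective the
linear layer is eliminated exactly by a least-squares projection through an
orthogonal-triangular (QR) factorisation, so the search runs only over the
few shared parameters (variable projection).

Two engines minimise the residual sum of squares: a trust-region-reflective
gradient method (scipy ``least_squares``) and a derivative-free compass
pattern search for rugged objectives.  Rates are optimised in log-space to
enforce positivity and improve conditioning; a rate pinned at the lower bound
is reported as a long-lived ("infinite") component.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import qr, solve_triangular
from scipy.optimize import least_squares

from .decomposition import svd_decompose, weight_left_vectors
from .io import DataMatrix
from .kinetics import KineticScheme, solve_concentrations
from .response import IRFModel, exp_conv_irf

__all__ = ["FitProblem", "FitResult", "project_linear", "fit_global", "fit_svd_traces",
           "model_comparison"]

RATE_LOWER_BOUND = 1e-12  # 1/time; a fitted rate at this bound means "long-lived"
RATE_UPPER_BOUND = 1e6


@dataclass
class FitProblem:
    """Data, connectivity scheme and fitting options.

    The rate values stored in ``scheme`` are the starting values; rates equal
    to zero are held fixed (long-lived components).  ``fit_target`` selects
    the full matrix or the first ``n_keep`` (optionally singular-value
    weighted) left singular vectors.
    """

    data: DataMatrix
    scheme: KineticScheme
    irf: IRFModel | None = None
    irf_free: tuple[str, ...] = ()  # subset of {"t0", "fwhm"}
    fit_target: str = "full"  # full | svd-traces | weighted-svd-traces
    engine: str = "gradient"  # gradient | pattern-search
    n_keep: int | None = None
    offset_enabled: bool = True
    rate_bounds: tuple[float, float] = (RATE_LOWER_BOUND, RATE_UPPER_BOUND)

    def __post_init__(self) -> None:
        if self.fit_target not in ("full", "svd-traces", "weighted-svd-traces"):
            raise ValueError(f"unknown fit_target {self.fit_target!r}")
        if self.fit_target != "full" and self.n_keep is None:
            raise ValueError("svd fit targets require n_keep")
        lo, hi = self.rate_bounds
        for (_, _), k in self.scheme.rate_constants.items():
            if k > 0 and not lo <= k <= hi:
                raise ValueError("starting rates must lie within rate_bounds")


@dataclass
class FitResult:
    """Fitted rates, spectra, offsets and diagnostics."""

    rate_keys: list[tuple[str, str]]
    rates: np.ndarray
    rate_errors: np.ndarray
    long_lived: list[bool]
    spectra: np.ndarray  # (n_species, n_channels)
    offsets: np.ndarray  # (n_channels,)
    residual_matrix: np.ndarray
    sum_of_squares: float
    converged: bool
    engine_report: dict = field(default_factory=dict)
    rank_deficient: bool = False

    @property
    def lifetimes(self) -> list[tuple[float, float, bool]]:
        """(lifetime, standard error, long_lived) sorted ascending; long-lived last."""
        out = []
        for k, se, ll in zip(self.rates, self.rate_errors, self.long_lived):
            if ll or k <= RATE_LOWER_BOUND * 10:
                out.append((math.inf, math.inf, True))
            else:
                out.append((1.0 / k, se / k**2, False))
        return sorted(out, key=lambda t: t[0])


def project_linear(concentrations, data, offset_enabled: bool = True):
    """Solve data ≈ concentrations · spectra (+ offset row) channel by channel.

    ``concentrations`` is an (m, s) array (or ConcentrationMatrix) sharing the
    time axis with ``data``; the least-squares solution comes from a QR
    factorisation and is unique when the design has full column rank.  A
    rank-deficient design (duplicated rates) produces a warning and the
    minimum-norm solution.

    Returns ``(spectra, offsets, residual_matrix)``; offsets are zero when
    ``offset_enabled`` is False.
    """
    C = np.asarray(getattr(concentrations, "values", concentrations), dtype=float)
    D = np.asarray(getattr(data, "values", data), dtype=float)
    if C.shape[0] != D.shape[0]:
        raise ValueError("time axes of concentrations and data differ")
    spectra, offsets, resid, deficient = _project(C, D, offset_enabled)
    if deficient:
        warnings.warn("rank-deficient concentration design; minimum-norm spectra returned")
    return spectra, offsets, resid


def _qr_rank(A: np.ndarray):
    Q, R, piv = qr(A, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = max(A.shape) * np.finfo(float).eps * (diag[0] if diag.size else 0.0)
    return Q, R, piv, int(np.sum(diag > tol))


def _project(C: np.ndarray, D: np.ndarray, offset: bool):
    A = np.hstack([C, np.ones((C.shape[0], 1))]) if offset else C
    Q, R, piv, rank = _qr_rank(A)
    if rank < A.shape[1] and offset:
        # A closed (mass-conserving) scheme makes the offset column an exact
        # linear combination of the concentration columns; the offset is then
        # unidentifiable and is dropped in favour of physical spectra.
        _, _, _, rank_c = _qr_rank(C)
        if rank_c == C.shape[1]:
            spectra, _, resid, deficient = _project(C, D, offset=False)
            return spectra, np.zeros(D.shape[1]), resid, deficient
    if rank == A.shape[1]:
        X = np.empty((A.shape[1], D.shape[1]))
        X[piv] = solve_triangular(R, Q.T @ D)
        deficient = False
    else:
        X = np.linalg.lstsq(A, D, rcond=None)[0]
        deficient = True
    resid = D - A @ X
    if offset:
        return X[:-1], X[-1], resid, deficient
    return X, np.zeros(D.shape[1]), resid, deficient


def _free_rate_keys(scheme: KineticScheme) -> list[tuple[str, str]]:
    return [key for key, k in scheme.rate_constants.items() if k > 0]


def _scheme_with_rates(scheme: KineticScheme, keys, rates) -> KineticScheme:
    rc = dict(scheme.rate_constants)
    for key, k in zip(keys, rates):
        rc[key] = float(k)
    return KineticScheme(list(scheme.species_names), rc, dict(scheme.initial_concentrations))


def _concentration_design(scheme: KineticScheme, times: np.ndarray,
                          irf: IRFModel | None, channels: np.ndarray):
    """(m, s) design, or (n_ch, m, s) when the IRF makes it channel dependent."""
    if irf is None:
        return solve_concentrations(scheme, times, 1e-9).values
    K = scheme.rate_matrix()
    c0 = scheme.initial_vector()
    w, V = np.linalg.eig(K)
    if np.max(np.abs(np.imag(w))) > 1e-9 * (1.0 + np.max(np.abs(w))):
        raise ValueError("oscillatory (complex-eigenvalue) schemes are unsupported with an IRF")
    if np.linalg.cond(V) > 1e10:
        raise ValueError("IRF convolution needs a diagonalisable rate matrix")
    w, V = np.real(w), np.real(V)
    a = np.linalg.solve(V, c0)
    rates = -w  # decay rates >= 0 for physical schemes
    if np.any(rates < -1e-9):
        raise ValueError("growing modes are not supported with an IRF")
    mode_weights = (V * a).T  # (mode, species)
    designs = np.empty((channels.size, times.size, c0.size))
    for jc, lam in enumerate(channels):
        basis = np.column_stack(
            [exp_conv_irf(times, max(r, 0.0), irf, lam) for r in rates]
        )
        designs[jc] = basis @ mode_weights
    return designs


def _evaluate(problem: FitProblem, D: np.ndarray, channels, keys, log_rates, irf_vals):
    scheme = _scheme_with_rates(problem.scheme, keys, np.exp(log_rates))
    irf = problem.irf
    if irf is not None and irf_vals:
        params = dict(zip(problem.irf_free, irf_vals))
        irf = IRFModel(
            t0=params.get("t0", irf.t0),
            fwhm=math.exp(params["fwhm"]) if "fwhm" in params else irf.fwhm,
            chirp_coeffs=irf.chirp_coeffs,
            lambda_c=irf.lambda_c,
        )
    C = _concentration_design(scheme, problem.data.times, irf, channels)
    if C.ndim == 2:
        spectra, offsets, resid, deficient = _project(C, D, problem.offset_enabled)
    else:  # channel-dependent design: project each channel separately
        n_sp = C.shape[2]
        spectra = np.empty((n_sp, D.shape[1]))
        offsets = np.zeros(D.shape[1])
        resid = np.empty_like(D)
        deficient = False
        for j in range(D.shape[1]):
            s, o, r, defj = _project(C[j], D[:, [j]], problem.offset_enabled)
            spectra[:, j] = s[:, 0]
            offsets[j] = o[0]
            resid[:, j] = r[:, 0]
            deficient = deficient or defj
    return spectra, offsets, resid, deficient


def _target_matrix(problem: FitProblem):
    """The matrix actually fitted, plus its channel axis."""
    if problem.fit_target == "full":
        return problem.data.values, problem.data.channels
    svd = svd_decompose(problem.data)
    n = problem.n_keep
    if problem.fit_target == "weighted-svd-traces":
        traces = weight_left_vectors(svd, n)
    else:
        traces = svd.left_vectors[:, :n]
    # basis traces have no wavelength: use the component index as channel axis
    return traces, np.arange(1, n + 1, dtype=float)


def _pattern_search(fun, x0, lo, hi, mesh0, tol=1e-6, max_iter=20000):
    """Compass pattern search: poll ±mesh along each axis, expand 2, contract 0.5."""
    x = np.clip(np.asarray(x0, dtype=float), lo, hi)
    f = fun(x)
    mesh = float(mesh0)
    n_eval, it = 1, 0
    while mesh > tol and it < max_iter:
        it += 1
        improved = False
        for i in range(x.size):
            for sgn in (+1.0, -1.0):
                cand = x.copy()
                cand[i] = np.clip(cand[i] + sgn * mesh, lo[i], hi[i])
                if cand[i] == x[i]:
                    continue
                fc = fun(cand)
                n_eval += 1
                if fc < f:
                    x, f = cand, fc
                    improved = True
                    break
            if improved:
                break
        mesh = mesh * 2.0 if improved else mesh * 0.5
        mesh = min(mesh, float(np.max(hi - lo)))
    return x, f, {"iterations": it, "n_eval": n_eval, "final_mesh": mesh}


def fit_global(problem: FitProblem) -> FitResult:
    """Minimise the residual sum of squares over the shared nonlinear parameters.

    Rates start from the values stored in the scheme (zero rates stay fixed as
    long-lived components) and are fitted in log-space within
    ``problem.rate_bounds``; per-channel spectra and offsets are eliminated by
    :func:`project_linear` at every evaluation.  Standard errors come from the
    linearised covariance (JᵀJ)⁻¹·SS/dof at the optimum.
    """
    D, channels = _target_matrix(problem)
    if not np.all(np.isfinite(D)):
        raise ValueError("data contains NaN/Inf; mask or crop before fitting")
    keys = _free_rate_keys(problem.scheme)
    if problem.fit_target != "full" and problem.n_keep < len(keys):
        warnings.warn("fewer SVD traces than free rates; fit may be underdetermined")
    x0 = np.log([problem.scheme.rate_constants[k] for k in keys])
    lo = np.full(x0.size, math.log(problem.rate_bounds[0]))
    hi = np.full(x0.size, math.log(problem.rate_bounds[1]))
    n_irf = len(problem.irf_free)
    if n_irf:
        irf0 = []
        for name in problem.irf_free:
            if name == "t0":
                irf0.append(problem.irf.t0)
            elif name == "fwhm":
                irf0.append(math.log(problem.irf.fwhm))
            else:
                raise ValueError(f"unknown free IRF parameter {name!r}")
        span = problem.data.times[-1] - problem.data.times[0]
        x0 = np.concatenate([x0, irf0])
        lo = np.concatenate([lo, [v - span if n == "t0" else v - math.log(1e3)
                                  for n, v in zip(problem.irf_free, irf0)]])
        hi = np.concatenate([hi, [v + span if n == "t0" else v + math.log(1e3)
                                  for n, v in zip(problem.irf_free, irf0)]])

    def split(x):
        return x[: len(keys)], list(x[len(keys):])

    def residuals(x):
        lr, iv = split(x)
        return _evaluate(problem, D, channels, keys, lr, iv)[2].ravel()

    if x0.size == 0:  # nothing nonlinear to optimise: pure linear projection
        x_opt = x0
        jac = np.empty((D.size, 0))
        converged = True
        report = {"engine": problem.engine, "iterations": 0}
    elif problem.engine == "gradient":
        sol = least_squares(residuals, x0, bounds=(lo, hi), method="trf",
                            ftol=1e-12, xtol=1e-12, gtol=1e-12)
        x_opt, jac = sol.x, sol.jac
        converged = bool(sol.success)
        report = {"engine": "gradient", "iterations": int(sol.nfev),
                  "status": int(sol.status), "message": sol.message}
    elif problem.engine == "pattern-search":
        mesh0 = 0.25 * float(np.max(hi - lo))
        x_opt, _, ps_report = _pattern_search(
            lambda x: float(np.sum(residuals(x) ** 2)), x0, lo, hi, mesh0
        )
        jac = _numeric_jacobian(residuals, x_opt)
        converged = ps_report["final_mesh"] <= 1e-6
        report = {"engine": "pattern-search", **ps_report}
    else:
        raise ValueError(f"unknown engine {problem.engine!r}")

    log_rates, irf_vals = split(x_opt)
    spectra, offsets, resid, deficient = _evaluate(problem, D, channels, keys,
                                                   log_rates, irf_vals)
    ss = float(np.sum(resid**2))
    se_all = _standard_errors(jac, ss, resid.size)

    all_keys = list(problem.scheme.rate_constants)
    rates, errs, long_lived = [], [], []
    fitted = dict(zip(keys, np.exp(log_rates)))
    fitted_se = dict(zip(keys, se_all[: len(keys)]))
    for key in all_keys:
        if key in fitted:
            k = fitted[key]
            rates.append(k)
            errs.append(k * fitted_se[key])  # chain rule from log-space
            long_lived.append(k <= problem.rate_bounds[0] * 10)
        else:
            rates.append(problem.scheme.rate_constants[key])
            errs.append(0.0)
            long_lived.append(True)
    # species without any outgoing reaction are long-lived components too
    sinks_with_rate = {src for (src, _sink) in problem.scheme.rate_constants}
    for s in problem.scheme.species_names:
        if s not in sinks_with_rate:
            all_keys.append((s, "loss"))
            rates.append(0.0)
            errs.append(0.0)
            long_lived.append(True)
    report.update({"fitted_irf": dict(zip(problem.irf_free, irf_vals))})
    return FitResult(
        rate_keys=all_keys,
        rates=np.array(rates),
        rate_errors=np.array(errs),
        long_lived=long_lived,
        spectra=spectra,
        offsets=offsets,
        residual_matrix=resid,
        sum_of_squares=ss,
        converged=converged,
        engine_report=report,
        rank_deficient=deficient,
    )


def _numeric_jacobian(fun, x, eps=1e-6):
    f0 = fun(x)
    J = np.empty((f0.size, x.size))
    for i in range(x.size):
        xp = x.copy()
        xp[i] += eps
        J[:, i] = (fun(xp) - f0) / eps
    return J


def _standard_errors(jac: np.ndarray, ss: float, n_resid: int) -> np.ndarray:
    dof = max(n_resid - jac.shape[1], 1)
    try:
        cov = np.linalg.pinv(jac.T @ jac) * ss / dof
        return np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        return np.full(jac.shape[1], np.nan)


def fit_svd_traces(problem: FitProblem, n_keep: int | None = None,
                   weighted: bool = False) -> FitResult:
    """Fit the first ``n_keep`` (optionally weighted) left singular vectors.

    The shared rates are identical to a full-data fit on noiseless data; the
    per-trace amplitudes are basis amplitudes without enforced physical
    meaning.
    """
    from dataclasses import replace

    n = n_keep if n_keep is not None else problem.n_keep
    if n is None:
        raise ValueError("n_keep is required")
    target = "weighted-svd-traces" if weighted else "svd-traces"
    return fit_global(replace(problem, fit_target=target, n_keep=n))


def model_comparison(results: list[FitResult], amplitude_floor: float = 0.3):
    """Goodness-of-fit table across fits of the same data.

    Each row gives the component count, the sum of squares and the relative
    improvement over the previous (larger-SS) entry.  For every fit, spectrum
    pairs with compensating amplitudes are flagged: two components whose
    amplitudes at one or more shared channels have opposite signs while each
    exceeds ``amplitude_floor`` of that spectrum's own maximum — amplitude
    poured into one component and subtracted from another, the signature of
    an inadequate (e.g. parallel) model.
    """
    if len(results) < 2:
        raise ValueError("need at least two fits to compare")
    shape = results[0].residual_matrix.shape
    for res in results[1:]:
        if res.residual_matrix.shape != shape:
            raise ValueError("fits were not performed on identical data")
    rows = []
    prev_ss = None
    for res in results:
        n_comp = res.spectra.shape[0]
        flags = _compensating_pairs(res.spectra, amplitude_floor)
        improvement = 0.0 if prev_ss is None else (prev_ss - res.sum_of_squares) / prev_ss
        rows.append({
            "n_components": n_comp,
            "sum_of_squares": res.sum_of_squares,
            "relative_improvement": improvement,
            "compensating_pairs": flags,
        })
        prev_ss = res.sum_of_squares
    return rows


def _compensating_pairs(spectra: np.ndarray, amplitude_floor: float) -> list[tuple[int, int]]:
    flags = []
    n = spectra.shape[0]
    for i in range(n):
        for j in range(i + 1, n):
            si, sj = spectra[i], spectra[j]
            mi, mj = np.max(np.abs(si)), np.max(np.abs(sj))
            if mi == 0 or mj == 0:
                continue
            opposite = np.sign(si) * np.sign(sj) < 0
            substantial = (np.abs(si) > amplitude_floor * mi) & (np.abs(sj) > amplitude_floor * mj)
            if np.any(opposite & substantial):
                flags.append((i, j))
    return flags
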