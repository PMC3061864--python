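"""Connectivity schemes (compartmental first-order kinetics) and their solutions.

A :class:`KineticScheme` is a set of species coupled by first-order reactions
``source -> sink`` with rate constant k ≥ 0; ``sink`` may be another species or
the special label ``"loss"`` (decay out of the observed system).  The scheme
defines the linear ODE system dc/dt = K·c, whose solution gives the
time-dependent concentration (population) of every species.

k = 0 encodes a non-decaying, long-lived ("infinite") component.

The default solution path is exact: eigendecomposition of the rate matrix
(falling back to a matrix exponential per time point when K is defective or
ill-conditioned), with an LSODA numerical integrator available for
cross-checks and imported schemes.
"""

from __future__ import annotations

import math
import re
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.linalg import expm

__all__ = [
    "LOSS",
    "KineticScheme",
    "ConcentrationMatrix",
    "UnsupportedModelError",
    "build_parallel_scheme",
    "build_sequential_scheme",
    "import_sbml",
    "solve_concentrations",
    "scheme_from_config",
    "scheme_to_config",
]

LOSS = "loss"


class UnsupportedModelError(ValueError):
    """An imported model uses kinetics outside the first-order mass-action subset."""


@dataclass
class KineticScheme:
    """Species, first-order connectivity, and initial concentrations.

    ``rate_constants`` maps ``(source, sink)`` to k (1/time); ``sink`` is a
    species name or :data:`LOSS`.
    """

    species_names: list[str]
    rate_constants: dict[tuple[str, str], float]
    initial_concentrations: dict[str, float]

    def __post_init__(self) -> None:
        if not self.species_names:
            raise ValueError("scheme must contain at least one species")
        if len(set(self.species_names)) != len(self.species_names):
            raise ValueError("duplicate species names")
        known = set(self.species_names)
        for (src, sink), k in self.rate_constants.items():
            if src not in known:
                raise ValueError(f"unknown source species {src!r}")
            if sink != LOSS and sink not in known:
                raise ValueError(f"unknown sink species {sink!r}")
            if src == sink:
                raise ValueError(f"reaction {src!r} -> itself is not allowed")
            if not (math.isfinite(k) and k >= 0):
                raise ValueError(f"rate constant for {src}->{sink} must be finite and >= 0")
        # normalise: every species carries an explicit initial amount
        self.initial_concentrations = {
            s: float(self.initial_concentrations.get(s, 0.0)) for s in self.species_names
        }
        if not any(c != 0 for c in self.initial_concentrations.values()):
            raise ValueError("at least one species needs a nonzero initial concentration")

    @property
    def n_species(self) -> int:
        return len(self.species_names)

    @property
    def is_closed(self) -> bool:
        """True when every sink is an explicit species (mass is conserved)."""
        return all(sink != LOSS for (_, sink) in self.rate_constants) or not self.rate_constants

    def rate_matrix(self) -> np.ndarray:
        """The matrix K of dc/dt = K·c (columns: source species)."""
        idx = {s: i for i, s in enumerate(self.species_names)}
        K = np.zeros((self.n_species, self.n_species))
        for (src, sink), k in self.rate_constants.items():
            K[idx[src], idx[src]] -= k
            if sink != LOSS:
                K[idx[sink], idx[src]] += k
        return K

    def initial_vector(self) -> np.ndarray:
        return np.array([self.initial_concentrations.get(s, 0.0) for s in self.species_names])


@dataclass
class ConcentrationMatrix:
    """Per-time, per-species concentrations on a strictly increasing time grid."""

    times: np.ndarray
    species_names: list[str]
    values: np.ndarray  # (n_times, n_species)
    solver_tolerance: float = 1e-6

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.times.size, len(self.species_names)):
            raise ValueError("values shape inconsistent with axes")


def build_parallel_scheme(rates, labels: list[str] | None = None) -> KineticScheme:
    """Independently decaying species, one per rate, each with unit amount.

    Each species decays straight to :data:`LOSS`; a zero rate yields a
    constant (long-lived) component.
    """
    rates = [float(r) for r in rates]
    if not rates:
        raise ValueError("need at least one rate")
    if any(r < 0 for r in rates):
        raise ValueError("rates must be >= 0")
    names = labels or [f"A{i + 1}" for i in range(len(rates))]
    return KineticScheme(
        species_names=names,
        rate_constants={(n, LOSS): r for n, r in zip(names, rates) if r > 0},
        initial_concentrations={n: 1.0 for n in names},
    )


def build_sequential_scheme(rates, labels: list[str] | None = None) -> KineticScheme:
    """Chain A1 -> A2 -> ... -> An; only A1 starts populated (unit amplitude).

    The i-th rate moves species i to species i+1; the final rate (which may be
    0 for a terminal long-lived species) moves the last species to LOSS.
    """
    rates = [float(r) for r in rates]
    if not rates:
        raise ValueError("need at least one rate")
    if any(r < 0 for r in rates):
        raise ValueError("rates must be >= 0")
    names = labels or [f"A{i + 1}" for i in range(len(rates))]
    rc: dict[tuple[str, str], float] = {}
    for i, r in enumerate(rates):
        if r == 0:
            continue
        sink = names[i + 1] if i + 1 < len(names) else LOSS
        rc[(names[i], sink)] = r
    return KineticScheme(
        species_names=names,
        rate_constants=rc,
        initial_concentrations={names[0]: 1.0},
    )


_SBML_NS = re.compile(r"\{.*\}")


def _local(tag: str) -> str:
    return _SBML_NS.sub("", tag)


def import_sbml(document: str) -> KineticScheme:
    """Build a scheme from SBML text restricted to first-order mass action.

    Every reaction must be irreversible with exactly one reactant (rate
    ``k·[reactant]``); reversible reactions are expanded into two irreversible
    ones using kinetic-law parameters ``kf``/``kr`` (or the first two local
    parameters).  Anything else raises :class:`UnsupportedModelError`.
    """
    try:
        root = ET.fromstring(document)
    except ET.ParseError as exc:
        raise ValueError(f"malformed SBML/XML: {exc}") from exc

    def find_all(parent, name):
        return [el for el in parent.iter() if _local(el.tag) == name]

    species, initials = [], {}
    for sp in find_all(root, "species"):
        sid = sp.get("id")
        species.append(sid)
        amt = sp.get("initialAmount") or sp.get("initialConcentration") or "0"
        initials[sid] = float(amt)

    global_params = {
        p.get("id"): float(p.get("value", "nan"))
        for mp in find_all(root, "listOfParameters")
        for p in mp
        if _local(p.tag) == "parameter"
    }

    rc: dict[tuple[str, str], float] = {}
    for rxn in find_all(root, "reaction"):
        rid = rxn.get("id", "<unnamed>")
        reactants = [
            sr.get("species")
            for lor in rxn
            if _local(lor.tag) == "listOfReactants"
            for sr in lor
            if _local(sr.tag) == "speciesReference"
        ]
        products = [
            sr.get("species")
            for lop in rxn
            if _local(lop.tag) == "listOfProducts"
            for sr in lop
            if _local(sr.tag) == "speciesReference"
        ]
        if len(reactants) != 1:
            raise UnsupportedModelError(
                f"reaction {rid!r} has {len(reactants)} reactants; only first-order "
                "mass action with one reactant is supported"
            )
        if len(products) > 1:
            raise UnsupportedModelError(f"reaction {rid!r} has more than one product")
        local_params = {
            p.get("id"): float(p.get("value", "nan"))
            for kl in rxn
            if _local(kl.tag) == "kineticLaw"
            for lp in kl
            if _local(lp.tag) in ("listOfParameters", "listOfLocalParameters")
            for p in lp
        }
        params = {**global_params, **local_params}
        reversible = rxn.get("reversible", "false").lower() == "true"
        src = reactants[0]
        sink = products[0] if products else LOSS
        if reversible:
            if sink == LOSS:
                raise UnsupportedModelError(f"reversible reaction {rid!r} needs a product")
            named = [params.get("kf"), params.get("kr")]
            if named[0] is None or named[1] is None:
                vals = list(params.values())
                if len(vals) < 2:
                    raise UnsupportedModelError(
                        f"reversible reaction {rid!r} needs two rate parameters (kf, kr)"
                    )
                named = vals[:2]
            rc[(src, sink)] = rc.get((src, sink), 0.0) + named[0]
            rc[(sink, src)] = rc.get((sink, src), 0.0) + named[1]
        else:
            if not params:
                raise UnsupportedModelError(f"reaction {rid!r} has no rate parameter")
            k = params.get("k", next(iter(params.values())))
            rc[(src, sink)] = rc.get((src, sink), 0.0) + k

    if not species:
        raise UnsupportedModelError("document defines no species")
    if not any(v != 0 for v in initials.values()):
        # default convention for templates that omit amounts: populate the first species
        initials[species[0]] = 1.0
    return KineticScheme(species, rc, initials)


def solve_concentrations(
    scheme: KineticScheme,
    times,
    tolerance: float = 1e-6,
    solver: str = "exact",
) -> ConcentrationMatrix:
    """Solve dc/dt = K·c on ``times``.

    solver="exact" uses the eigendecomposition of K (matrix exponential per
    time point when K is defective); solver="ivp" integrates with LSODA at the
    requested relative ``tolerance``.  Both agree to within ``tolerance``.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size == 0:
        raise ValueError("times must be a non-empty 1-D grid")
    if times.size > 1 and not np.all(np.diff(times) > 0):
        raise ValueError("times must be sorted strictly ascending")
    if not (1e-12 <= tolerance <= 1e-3):
        raise ValueError("tolerance must lie in [1e-12, 1e-3]")
    K = scheme.rate_matrix()
    c0 = scheme.initial_vector()

    if solver == "exact":
        vals = _solve_exact(K, c0, times)
    elif solver == "ivp":
        t0 = min(times[0], 0.0)
        sol = solve_ivp(
            lambda _t, c: K @ c,
            (t0, times[-1]),
            c0,
            t_eval=times,
            method="LSODA",
            rtol=tolerance,
            atol=tolerance * max(1.0, float(np.max(np.abs(c0)))) * 1e-3,
        )
        if not sol.success:
            raise RuntimeError(f"ODE integration failed: {sol.message}")
        vals = sol.y.T
    else:
        raise ValueError(f"unknown solver {solver!r}")
    return ConcentrationMatrix(times, list(scheme.species_names), vals, tolerance)


def _solve_exact(K: np.ndarray, c0: np.ndarray, times: np.ndarray) -> np.ndarray:
    # Eigendecomposition path: c(t) = V diag(exp(w t)) V^-1 c0, vectorised over t.
    try:
        w, V = np.linalg.eig(K)
        cond = np.linalg.cond(V)
    except np.linalg.LinAlgError:
        cond = np.inf
    if np.isfinite(cond) and cond < 1e8:
        a = np.linalg.solve(V, c0.astype(complex))
        out = (np.exp(np.outer(times, w)) * a) @ V.T
        return np.real(out)
    # Defective / near-degenerate K (e.g. equal-rate sequential chains): Pade expm.
    out = np.empty((times.size, c0.size))
    for i, t in enumerate(times):
        out[i] = expm(K * t) @ c0
    return out


# -- plain declarative config ------------------------------------------------

_REACTION_RE = re.compile(r"^\s*(\S+)\s*->\s*(\S+)\s*:\s*(\S+)\s*$")


def scheme_to_config(scheme: KineticScheme) -> str:
    """Serialise to the declarative block: species, ``A -> B : k`` reactions, initials."""
    lines = ["[species]"]
    lines += [f"{s} = {scheme.initial_concentrations.get(s, 0.0)!r}" for s in scheme.species_names]
    lines.append("[reactions]")
    lines += [f"{src} -> {sink} : {k!r}" for (src, sink), k in scheme.rate_constants.items()]
    return "\n".join(lines) + "\n"


def scheme_from_config(text: str) -> KineticScheme:
    """Parse the block written by :func:`scheme_to_config`."""
    section = None
    species: list[str] = []
    initials: dict[str, float] = {}
    rc: dict[tuple[str, str], float] = {}
    for ln, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("["):
            section = line.strip("[]").lower()
            continue
        if section == "species":
            name, _, val = line.partition("=")
            species.append(name.strip())
            initials[name.strip()] = float(val) if val.strip() else 0.0
        elif section == "reactions":
            m = _REACTION_RE.match(line)
            if not m:
                raise ValueError(f"line {ln}: cannot parse reaction {line!r}")
            rc[(m.group(1), m.group(2))] = float(m.group(3))
        else:
            raise ValueError(f"line {ln}: content outside a [species]/[reactions] section")
    return KineticScheme(species, rc, initials)
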