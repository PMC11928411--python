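"""Synthetic two-group cohorts calibrated to a reference rat study
(5 control vs 9 heart-failure animals).

Each congestion variable (CVP, RMP, TTP, edema) is lognormal per group,
moment-matched to the reference group mean and SD = SE*sqrt(n); the
perfusion indices are normal on the raw scale. Subjects are coupled
through a Gaussian copula: one latent multivariate-normal draw per
subject, shared across variables, with a within-group latent correlation
matrix.

Planted correlations are *pooled across groups* (the scale on which
two-group scatter plots report R): the generator solves, per planted pair,
for the within-group latent correlation that makes the analytic pooled
(two-group mixture) Pearson correlation - computed on the IRPI-raw x
log-congestion scale - equal the requested target. Non-planted entries
follow a single-congestion-factor structure; the assembled matrix is
validated positive semi-definite.

The reference combined-ROI SE "0.54" exceeds its mean and is treated as a
misprint for 0.054 in the defaults (flagged, not silently altered:
see ``CohortSpec.notes``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..errors import ValidationError

VARIABLE_ORDER = (
    "cvp",
    "rmp",
    "ttp_cortex",
    "ttp_medulla",
    "irpi_interlobular",
    "irpi_interlobar",
    "irpi_combined",
    "edema",
)


@dataclass(frozen=True)
class GroupParams:
    """Per-variable group calibration (reference scale)."""

    mean_control: float
    se_control: float
    mean_hf: float
    se_hf: float
    family: str = "lognormal"  # "lognormal" | "normal"
    output_scale: float = 1.0  # printed value / stored value (100 for %)

    def __post_init__(self):
        if self.se_control <= 0 or self.se_hf <= 0:
            raise ValidationError("all SE must be > 0")
        if self.family not in ("lognormal", "normal"):
            raise ValidationError(f"family: unknown '{self.family}'")
        if self.family == "lognormal" and (
            self.mean_control <= 0 or self.mean_hf <= 0
        ):
            raise ValidationError("lognormal variable: means must be > 0")


def _reference_defaults() -> dict[str, GroupParams]:
    return {
        "cvp": GroupParams(10.36, 1.54, 18.34, 2.95),
        "rmp": GroupParams(2.80, 0.70, 7.51, 1.79),
        "ttp_cortex": GroupParams(1.60, 0.32, 2.20, 0.76),
        "ttp_medulla": GroupParams(1.98, 0.87, 4.39, 2.37),
        "irpi_interlobular": GroupParams(0.443, 0.09, 0.72, 0.06, family="normal"),
        "irpi_interlobar": GroupParams(0.16, 0.05, 0.21, 0.08, family="normal"),
        "irpi_combined": GroupParams(0.24, 0.054, 0.32, 0.03, family="normal"),
        "edema": GroupParams(15.8, 1.9, 22.3, 1.8, output_scale=100.0),
    }


DEFAULT_PLANTED_CORRELATIONS: dict[tuple[str, str], float] = {
    ("irpi_interlobular", "cvp"): 0.75,
    ("irpi_interlobular", "rmp"): 0.84,
    ("irpi_interlobular", "ttp_medulla"): 0.60,
    ("irpi_interlobular", "edema"): 0.55,
}

# single-congestion-factor loadings for non-planted correlation entries
_FACTOR_LOADINGS = {
    "cvp": 0.85,
    "rmp": 0.90,
    "ttp_cortex": 0.50,
    "ttp_medulla": 0.80,
    "edema": 0.70,
    "irpi_interlobar": 0.30,
    "irpi_combined": 0.45,
}


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions for the synthetic cohort.

    ``n_control``/``n_hf`` set how many subjects are drawn.
    ``se_reference_n`` are the group sizes behind the *reference* standard
    errors: the population SD of each variable is SE * sqrt(reference n),
    and stays fixed when larger cohorts are simulated from the same
    population (e.g. for moment-matching checks).
    """

    n_control: int = 5
    n_hf: int = 9
    se_reference_n: tuple[int, int] = (5, 9)
    variables: dict[str, GroupParams] = field(default_factory=_reference_defaults)
    planted_correlations: dict[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_PLANTED_CORRELATIONS)
    )
    seed: int = 0
    notes: str = (
        "combined-ROI IRPI SE uses 0.054; the reference 0.54 (> mean) is a "
        "presumed misprint"
    )

    def __post_init__(self):
        if self.n_control < 1 or self.n_hf < 1:
            raise ValidationError("n_control/n_hf: must be >= 1")
        for pair, rho in self.planted_correlations.items():
            if not (-1.0 <= rho <= 1.0):
                raise ValidationError(
                    f"planted correlation {pair}: must lie in [-1, 1], got {rho}"
                )
            for v in pair:
                if v not in self.variables:
                    raise ValidationError(
                        f"planted correlation {pair}: unknown variable '{v}'"
                    )


@dataclass
class CohortGroundTruth:
    spec: CohortSpec
    latent_order: tuple[str, ...]
    within_correlation: np.ndarray  # latent within-group matrix
    pooled_targets: dict[tuple[str, str], float]
    group_moments: dict[str, dict[str, tuple[float, float]]]
    """per variable, per group: (latent location, latent scale)."""


def _moments(p: GroupParams, mean: float, sd: float) -> tuple[float, float]:
    """Latent (location, scale): log-scale mu/sigma moment-matched to the
    reference mean and SD for a lognormal variable, raw mean/SD for a normal
    one."""
    if p.family == "normal":
        return mean, sd
    sigma2 = np.log1p((sd / mean) ** 2)
    return np.log(mean) - sigma2 / 2.0, float(np.sqrt(sigma2))


def _solve_within_rho(
    target: float,
    mu: tuple[float, float],
    s: tuple[float, float],
    nu: tuple[float, float],
    w: tuple[float, float],
    weights: tuple[float, float],
) -> float:
    """Within-group correlation whose two-group mixture gives `target` pooled.

    mu/s: latent location/scale of variable 1 per group; nu/w: same for
    variable 2; weights: group weights n_g/N. All on the analysis scale
    (raw for IRPI, log for congestion variables).
    """
    wc, wh = weights
    mbar1 = wc * mu[0] + wh * mu[1]
    mbar2 = wc * nu[0] + wh * nu[1]
    var1 = wc * (s[0] ** 2 + (mu[0] - mbar1) ** 2) + wh * (
        s[1] ** 2 + (mu[1] - mbar1) ** 2
    )
    var2 = wc * (w[0] ** 2 + (nu[0] - mbar2) ** 2) + wh * (
        w[1] ** 2 + (nu[1] - mbar2) ** 2
    )
    between = wc * (mu[0] - mbar1) * (nu[0] - mbar2) + wh * (mu[1] - mbar1) * (
        nu[1] - mbar2
    )
    within_scale = wc * s[0] * w[0] + wh * s[1] * w[1]
    rho_w = (target * np.sqrt(var1 * var2) - between) / within_scale
    return float(rho_w)


def _assemble_correlation(spec: CohortSpec) -> tuple[
    tuple[str, ...], np.ndarray, dict[str, dict[str, tuple[float, float]]]
]:
    order = tuple(v for v in VARIABLE_ORDER if v in spec.variables) + tuple(
        v for v in spec.variables if v not in VARIABLE_ORDER
    )
    n_c, n_h = spec.n_control, spec.n_hf
    ref_c, ref_h = spec.se_reference_n
    weights = (n_c / (n_c + n_h), n_h / (n_c + n_h))

    moments: dict[str, dict[str, tuple[float, float]]] = {}
    for v, p in spec.variables.items():
        moments[v] = {
            "control": _moments(
                p, p.mean_control, p.se_control * np.sqrt(ref_c)
            ),
            "HF": _moments(p, p.mean_hf, p.se_hf * np.sqrt(ref_h)),
        }

    k = len(order)
    # factor structure for non-planted entries; the planted variable's
    # loading is implied by its solved pairwise correlations
    solved: dict[tuple[str, str], float] = {}
    for (v1, v2), rho in spec.planted_correlations.items():
        m1, m2 = moments[v1], moments[v2]
        rho_w = _solve_within_rho(
            rho,
            (m1["control"][0], m1["HF"][0]),
            (m1["control"][1], m1["HF"][1]),
            (m2["control"][0], m2["HF"][0]),
            (m2["control"][1], m2["HF"][1]),
            weights,
        )
        if not (-1.0 <= rho_w <= 1.0):
            raise ValidationError(
                f"planted pooled correlation {rho} for {(v1, v2)} implies an "
                f"infeasible within-group correlation {rho_w:.3f}"
            )
        solved[(v1, v2)] = rho_w

    loadings = dict(_FACTOR_LOADINGS)
    planted_vars = {p[0] for p in solved}
    for pv in planted_vars:
        implied = [
            rw / loadings[other]
            for (a, other), rw in solved.items()
            if a == pv and other in loadings and loadings[other] > 0
        ]
        loadings[pv] = float(np.clip(np.mean(implied), -0.99, 0.99)) if implied else 0.5

    R = np.eye(k)
    for i, vi in enumerate(order):
        for j in range(i + 1, k):
            vj = order[j]
            key = (vi, vj) if (vi, vj) in solved else (vj, vi)
            if key in solved:
                val = solved[key]
            else:
                val = loadings.get(vi, 0.4) * loadings.get(vj, 0.4)
            R[i, j] = R[j, i] = val

    eig = np.linalg.eigvalsh(R)
    if eig.min() < -1e-8:
        raise ValidationError(
            "correlation target is not positive semi-definite "
            f"(min eigenvalue {eig.min():.3g}); offending planted pair(s): "
            f"{sorted(spec.planted_correlations)}"
        )
    return order, R, moments


def generate_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, CohortGroundTruth]:
    """Seeded cohort table plus the planted copula ground truth."""
    order, R, moments = _assemble_correlation(spec)
    rng = np.random.default_rng(spec.seed)

    # PSD factor via eigen-decomposition (tolerates rho = +-1 edges)
    evals, evecs = np.linalg.eigh(R)
    L = evecs @ np.diag(np.sqrt(np.clip(evals, 0.0, None)))

    rows = []
    sid = 0
    for group, n in (("control", spec.n_control), ("HF", spec.n_hf)):
        z = rng.standard_normal((n, len(order))) @ L.T
        for i in range(n):
            row: dict[str, object] = {"id": f"s{sid:03d}", "group": group}
            for j, v in enumerate(order):
                p = spec.variables[v]
                loc, scale = moments[v][group]
                val = loc + scale * z[i, j]
                if p.family == "lognormal":
                    val = np.exp(val)
                row[v] = val / p.output_scale
            rows.append(row)
            sid += 1
    table = pd.DataFrame(rows)
    truth = CohortGroundTruth(
        spec=spec,
        latent_order=order,
        within_correlation=R,
        pooled_targets=dict(spec.planted_correlations),
        group_moments=moments,
    )
    return table, truth
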