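"""Synthetic cohort generator for the association analysis.

Emulates an ageing birth-cohort sub-sample with per-eye retinal fractal
dimensions, childhood IQ, cognitive domain scores with their subtests,
vascular risk factors, and realistic missingness.  The continuous block
(childhood IQ, three latent cognitive domains, eight fractal measures) is
drawn from a multivariate normal with a configurable correlation
structure; true fractal-to-cognition effects are injected as linear
contributions so that parameter-recovery and type-I-error experiments have
a known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["CohortSpec", "generate_cohort", "EYES", "DIMENSIONS", "DOMAINS", "SUBTEST_LOADINGS", "DEFAULT_DOMAIN_SPEC"]

EYES = ("left", "right")
DIMENSIONS = ("dbox", "d0", "d1", "d2")
DOMAINS = ("g", "speed", "memory")

#: fractal measurement columns, eye-major: left dbox..d2 then right dbox..d2
FRACTAL_COLUMNS = tuple(f"{d}_{e}" for e in EYES for d in DIMENSIONS)

#: subtest -> (primary latent domain, loading); negative loadings are
#: reaction-time-style scores where smaller is better
SUBTEST_LOADINGS: dict[str, tuple[str, float]] = {
    "symbol_search": ("speed", 0.75),
    "digit_symbol_coding": ("speed", 0.80),
    "matrix_reasoning": ("g", 0.75),
    "letter_number_sequencing": ("g", 0.70),
    "block_design": ("g", 0.75),
    "digit_span_backwards": ("memory", 0.65),
    "simple_rt": ("speed", -0.70),
    "choice_rt": ("speed", -0.75),
    "inspection_time": ("speed", 0.60),
    "logical_memory_immediate": ("memory", 0.75),
    "logical_memory_delayed": ("memory", 0.75),
    "spatial_span_forwards": ("memory", 0.55),
    "spatial_span_backwards": ("memory", 0.60),
    "vpa_immediate": ("memory", 0.70),
    "vpa_delayed": ("memory", 0.70),
}

#: which subtests feed the first-principal-component score of each domain
DEFAULT_DOMAIN_SPEC: dict[str, list[str]] = {
    "g": [
        "symbol_search",
        "digit_symbol_coding",
        "matrix_reasoning",
        "letter_number_sequencing",
        "block_design",
        "digit_span_backwards",
    ],
    "speed": [
        "symbol_search",
        "digit_symbol_coding",
        "simple_rt",
        "choice_rt",
        "inspection_time",
    ],
    "memory": [
        "letter_number_sequencing",
        "digit_span_backwards",
        "logical_memory_immediate",
        "logical_memory_delayed",
        "spatial_span_forwards",
        "spatial_span_backwards",
        "vpa_immediate",
        "vpa_delayed",
    ],
}


def _default_fractal_moments() -> dict[str, tuple[float, float]]:
    return {
        "dbox_left": (1.42, 0.02),
        "d0_left": (1.68, 0.02),
        "d1_left": (1.64, 0.03),
        "d2_left": (1.62, 0.03),
        "dbox_right": (1.43, 0.02),
        "d0_right": (1.68, 0.02),
        "d1_right": (1.65, 0.03),
        "d2_right": (1.63, 0.03),
    }


@dataclass
class CohortSpec:
    """Population parameters of the synthetic cohort.

    Continuous-block defaults are the descriptive statistics of a ~73-year
    birth-cohort sub-sample with gradable fundus photographs: age 72.4 y
    (SD 0.71), 50.3% male, childhood IQ rescaled to mean 102 / SD 14 in
    this sub-sample, skeleton-based fractal dimension means of ~1.42-1.43
    (box counting) and 1.62-1.68 (sandbox D0-D2) with SDs of 0.02-0.03.
    Left and right eyes of the same dimension correlate 0.50 (midpoint of
    the observed 0.403-0.582 range); different dimensions within an eye
    correlate 0.85 (midpoint of the observed 0.708-0.982).
    """

    n: int = 648
    seed: int = 0
    age_mean: float = 72.4
    age_sd: float = 0.71
    prop_male: float = 0.503
    age11_iq_mean: float = 102.0
    age11_iq_sd: float = 14.0
    #: correlation of each latent domain with childhood IQ
    domain_iq_corr: dict[str, float] = field(
        default_factory=lambda: {"g": 0.70, "speed": 0.55, "memory": 0.55}
    )
    #: correlation between latent cognitive domains
    inter_domain_corr: float = 0.60
    fractal_moments: dict[str, tuple[float, float]] = field(
        default_factory=_default_fractal_moments
    )
    left_right_corr: float = 0.50
    inter_dimension_corr: float = 0.85
    #: correlation of childhood IQ with every fractal measure (lets the
    #: fractal-cognition association be induced solely through IQ)
    iq_fractal_corr: float = 0.0
    #: injected linear effects {(eye, dimension, domain): standardized beta}
    true_effects: dict[tuple[str, str, str], float] = field(default_factory=dict)
    covariate_prevalence: dict[str, float] = field(
        default_factory=lambda: {
            "hypertension": 0.483,
            "diabetes": 0.094,
            "cardiovascular_disease": 0.273,
            "stroke": 0.060,
        }
    )
    smoking_probs: dict[str, float] = field(
        default_factory=lambda: {"current": 0.080, "ex": 0.370, "never": 0.550}
    )
    mmse_low_rate: float = 6 / 663
    ungradable_rate: float = 9 / 663
    #: a participant loses the whole fractal set (acquisition failure) ...
    fractal_missing_all: float = 0.175
    #: ... and single measures additionally drop out independently
    fractal_missing_each: float = 0.005
    iq_missing_rate: float = 43 / 648
    domain_missing_rate: dict[str, float] = field(
        default_factory=lambda: {"g": 7 / 648, "speed": 32 / 648, "memory": 27 / 648}
    )

    @classmethod
    def from_yaml(cls, path) -> "CohortSpec":
        """Load a spec from a YAML mapping of field names to values.

        ``true_effects`` keys are written as "eye.dimension.domain".
        """
        import yaml
        from pathlib import Path

        raw = yaml.safe_load(Path(path).read_text()) or {}
        effects = raw.pop("true_effects", None)
        spec = cls(**raw)
        if effects:
            spec.true_effects = {
                tuple(k.split(".")): float(v) for k, v in effects.items()
            }
        return spec

    def validate(self) -> None:
        for name, val in (
            ("left_right_corr", self.left_right_corr),
            ("inter_dimension_corr", self.inter_dimension_corr),
            ("inter_domain_corr", self.inter_domain_corr),
            ("iq_fractal_corr", self.iq_fractal_corr),
            *((f"domain_iq_corr[{k}]", v) for k, v in self.domain_iq_corr.items()),
        ):
            if not -1.0 < val < 1.0:
                raise ValueError(f"{name} = {val} outside (-1, 1)")
        for name, p in {
            **self.covariate_prevalence,
            "mmse_low_rate": self.mmse_low_rate,
            "ungradable_rate": self.ungradable_rate,
            "prop_male": self.prop_male,
        }.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"prevalence {name} = {p} outside [0, 1]")


def continuous_correlation(spec: CohortSpec) -> tuple[np.ndarray, list[str]]:
    """Correlation matrix of [iq, g, speed, memory, 8 fractal measures].

    Raises ``ValueError`` naming the offending eigenvalue if the implied
    matrix is not positive semi-definite.
    """
    names = ["age11_iq", *DOMAINS, *FRACTAL_COLUMNS]
    k = len(names)
    corr = np.eye(k)

    def set_(a: str, b: str, v: float) -> None:
        i, j = names.index(a), names.index(b)
        corr[i, j] = corr[j, i] = v

    for dom in DOMAINS:
        set_("age11_iq", dom, spec.domain_iq_corr[dom])
    for i, a in enumerate(DOMAINS):
        for b in DOMAINS[i + 1 :]:
            set_(a, b, spec.inter_domain_corr)
    cross = spec.left_right_corr * spec.inter_dimension_corr
    for ca in FRACTAL_COLUMNS:
        set_("age11_iq", ca, spec.iq_fractal_corr)
        # any fractal-cognition correlation present at baseline is mediated
        # by childhood IQ: corr(domain, fractal) = corr(iq, fractal) * corr(iq, domain)
        for dom in DOMAINS:
            set_(dom, ca, spec.iq_fractal_corr * spec.domain_iq_corr[dom])
        for cb in FRACTAL_COLUMNS:
            if ca >= cb:
                continue
            da, ea = ca.rsplit("_", 1)[0], ca.rsplit("_", 1)[1]
            db, eb = cb.rsplit("_", 1)[0], cb.rsplit("_", 1)[1]
            if ea == eb:
                set_(ca, cb, spec.inter_dimension_corr)
            elif da == db:
                set_(ca, cb, spec.left_right_corr)
            else:
                set_(ca, cb, cross)
    eigvals = np.linalg.eigvalsh(corr)
    if eigvals[0] < -1e-10:
        raise ValueError(
            f"implied correlation matrix is not positive semi-definite "
            f"(smallest eigenvalue {eigvals[0]:.6g})"
        )
    return corr, names


def generate_cohort(spec: CohortSpec | None = None) -> pd.DataFrame:
    """Sample a participant table; deterministic given ``spec.seed``.

    Columns: id, age, sex (1 = male), age11_iq, mmse, gradable,
    hypertension / diabetes / cardiovascular_disease / stroke (0/1),
    smoking ({current, ex, never}), the 15 subtest scores, the three latent
    domain scores (g, speed, memory; standardized, with any true effects
    already injected), and the eight fractal measures
    ``{dbox,d0,d1,d2}_{left,right}``.
    """
    spec = spec or CohortSpec()
    spec.validate()
    corr, names = continuous_correlation(spec)
    rng = np.random.default_rng(spec.seed)
    n = spec.n

    chol = np.linalg.cholesky(corr + 1e-12 * np.eye(len(names)))
    z = rng.standard_normal((n, len(names))) @ chol.T
    block = pd.DataFrame(z, columns=names)

    df = pd.DataFrame({"id": [f"P{i:05d}" for i in range(n)]})
    df["age"] = spec.age_mean + spec.age_sd * rng.standard_normal(n)
    df["sex"] = (rng.random(n) < spec.prop_male).astype(int)
    df["age11_iq"] = spec.age11_iq_mean + spec.age11_iq_sd * block["age11_iq"]

    # fractal measures on their natural scale
    for col in FRACTAL_COLUMNS:
        mu, sd = spec.fractal_moments[col]
        df[col] = mu + sd * block[col]

    # inject true effects: domain = sqrt(1 - var(effect part)) * latent + b' z
    for dom in DOMAINS:
        betas = {
            col: spec.true_effects.get((eye, dim, dom), 0.0)
            for eye in EYES
            for dim in DIMENSIONS
            for col in [f"{dim}_{eye}"]
        }
        bvec = np.array([betas[c] for c in FRACTAL_COLUMNS])
        if np.any(bvec != 0.0):
            idx = [names.index(c) for c in FRACTAL_COLUMNS]
            sub = corr[np.ix_(idx, idx)]
            var_eff = float(bvec @ sub @ bvec)
            if var_eff >= 1.0:
                raise ValueError("injected effects imply variance >= 1 for " + dom)
            zf = block[list(FRACTAL_COLUMNS)].to_numpy()
            df[dom] = np.sqrt(1.0 - var_eff) * block[dom] + zf @ bvec
        else:
            df[dom] = block[dom]

    # subtests: simple one-factor measurement model on the latent domains
    for name, (dom, lam) in SUBTEST_LOADINGS.items():
        noise = rng.standard_normal(n) * np.sqrt(1.0 - lam**2)
        df[name] = lam * df[dom] + noise

    for cov, p in spec.covariate_prevalence.items():
        df[cov] = (rng.random(n) < p).astype(int)
    probs = np.array([spec.smoking_probs[k] for k in ("current", "ex", "never")])
    probs = probs / probs.sum()
    df["smoking"] = rng.choice(["current", "ex", "never"], size=n, p=probs)

    mmse = np.clip(np.round(28.8 + 1.2 * rng.standard_normal(n)), 24, 30)
    low = rng.random(n) < spec.mmse_low_rate
    mmse[low] = rng.integers(18, 24, size=int(low.sum()))
    df["mmse"] = mmse.astype(int)
    df["gradable"] = (rng.random(n) >= spec.ungradable_rate).astype(int)

    # missingness, completely at random
    lost_all = rng.random(n) < spec.fractal_missing_all
    for col in FRACTAL_COLUMNS:
        lost = lost_all | (rng.random(n) < spec.fractal_missing_each)
        df.loc[lost, col] = np.nan
    df.loc[rng.random(n) < spec.iq_missing_rate, "age11_iq"] = np.nan
    for dom in DOMAINS:
        df.loc[rng.random(n) < spec.domain_missing_rate[dom], dom] = np.nan

    return df
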