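"""Seeded generators for synthetic assay panels and energy fingerprints.

The study's raw assay time courses and molecular-dynamics energy matrices
are not deposited, so every pipeline stage is exercised on synthetic inputs
that carry the same statistical structure: exponential activity decay with
saturating concentration dependence and multiplicative assay noise for the
kinetics stage, and a low-rank-plus-noise compound x variable matrix with a
planted polynomial score->response relation for the chemometrics stage.
All generators are pure functions of their seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd

from .kinetics import ActivitySeries, AssaySeriesDesign, SchemeParams, simulate_activity

__all__ = [
    "PanelTruth",
    "FingerprintTruth",
    "DEFAULT_DESIGN",
    "KI_ENVELOPES",
    "generate_panel",
    "generate_fingerprints",
    "paper_compounds",
]

# 6 concentrations spanning the 0.5-200 uM assay range (log-spaced), 6
# incubation times out to 20 min: a realistic time-dependent inhibition grid.
DEFAULT_DESIGN = AssaySeriesDesign(
    inhibitor_concentrations=tuple(
        round(c, 10) for c in np.geomspace(2e-6, 2e-4, 6)
    ),
    incubation_times=(0.0, 2.0, 5.0, 10.0, 15.0, 20.0),
    replicates=1,
)

# Observed k_i envelopes (L mol^-1 min^-1) per enzyme; truth is sampled
# log-uniformly inside these because the constants span decades.
KI_ENVELOPES: Dict[str, Tuple[float, float]] = {
    "AChE": (1.0e3, 15.0e3),
    "BChE": (1.5e3, 24.0e3),
}
KA_ENVELOPE = (1.0e-5, 2.0e-4)  # mol/L (10-200 uM)


@dataclass(frozen=True)
class PanelTruth:
    """True kinetic constants behind a simulated compound panel."""

    enzyme: str
    compound_ids: Tuple[str, ...]
    k_max: Tuple[float, ...]  # 1/min
    K_a: Tuple[float, ...]  # mol/L

    @property
    def k_i(self) -> Tuple[float, ...]:
        return tuple(km / ka for km, ka in zip(self.k_max, self.K_a))


def generate_panel(
    n_compounds: int = 13,
    enzyme: str = "AChE",
    seed: int = 0,
    noise_cv: float = 0.03,
    design: AssaySeriesDesign = DEFAULT_DESIGN,
    v0: float = 1.0,
) -> Tuple[List[ActivitySeries], PanelTruth]:
    """Simulate a compound panel of time-dependent inhibition assays.

    k_i is sampled log-uniformly within the enzyme's observed envelope and
    K_a log-uniformly in 10-200 uM; k_max = k_i * K_a.  Each compound
    produces one ActivitySeries per design concentration via
    :func:`simulate_activity`.
    """
    if n_compounds < 1:
        raise ValueError("n_compounds must be >= 1")
    rng = np.random.default_rng(seed)
    lo, hi = KI_ENVELOPES.get(enzyme, (1.0e3, 24.0e3))
    k_i = np.exp(rng.uniform(np.log(lo), np.log(hi), n_compounds))
    K_a = np.exp(rng.uniform(np.log(KA_ENVELOPE[0]), np.log(KA_ENVELOPE[1]), n_compounds))
    k_max = k_i * K_a
    ids = tuple(f"cpd{i + 1}" for i in range(n_compounds))
    series: List[ActivitySeries] = []
    for cid, km, ka in zip(ids, k_max, K_a):
        series.extend(
            simulate_activity(
                SchemeParams(k_max=float(km), K_a=float(ka)),
                design, v0=v0, noise_cv=noise_cv, seed=rng,
                compound_id=cid, enzyme=enzyme,
            )
        )
    truth = PanelTruth(
        enzyme=enzyme, compound_ids=ids,
        k_max=tuple(map(float, k_max)), K_a=tuple(map(float, K_a)),
    )
    return series, truth


@dataclass(frozen=True)
class FingerprintTruth:
    """Ground truth of the low-rank fingerprint generator.

    Two orthonormal loading directions carry scores of standard deviation
    ``score_sds``; i.i.d. Gaussian noise of sd ``noise_sd`` is added on top.
    The response is a polynomial in the standardised scores (z1, z2):
    Y = 0.8 z1^3 - 1.2 z1 z2 + z2^2 plus Gaussian noise whose sd is
    ``response_noise_frac`` of sd(Y).
    """

    score_sds: Tuple[float, float] = (4.0, 2.5)
    noise_sd: float = 0.3
    response_noise_frac: float = 0.10
    cubic: bool = True  # False plants a purely linear response (diagnostics)
    seed: int = 0


def generate_fingerprints(
    n_compounds: int = 13,
    n_vars: int = 60,
    truth: FingerprintTruth = FingerprintTruth(),
) -> Tuple[pd.DataFrame, pd.Series, Dict[str, np.ndarray]]:
    """Low-rank-plus-noise fingerprint matrix with a planted response.

    Returns the compound x variable DataFrame, the response Series, and a
    dict with the true scores/loadings for oracle checks.
    """
    if n_vars < 3:
        raise ValueError("n_vars must be >= 3")
    if min(truth.score_sds) <= 0:
        raise ValueError("score standard deviations must be positive")
    rng = np.random.default_rng(truth.seed)
    # orthonormal loading directions via QR of a Gaussian matrix
    q, _ = np.linalg.qr(rng.standard_normal((n_vars, 2)))
    p1, p2 = q[:, 0], q[:, 1]
    s1 = rng.standard_normal(n_compounds) * truth.score_sds[0]
    s2 = rng.standard_normal(n_compounds) * truth.score_sds[1]
    X = np.outer(s1, p1) + np.outer(s2, p2)
    X += rng.standard_normal(X.shape) * truth.noise_sd
    z1 = s1 / truth.score_sds[0]
    z2 = s2 / truth.score_sds[1]
    if truth.cubic:
        y = 0.8 * z1**3 - 1.2 * z1 * z2 + z2**2
    else:
        y = 1.5 * z1 - 0.7 * z2
    if truth.response_noise_frac > 0:
        y = y + rng.standard_normal(n_compounds) * (truth.response_noise_frac * y.std())
    ids = [f"cpd{i + 1}" for i in range(n_compounds)]
    cols = [f"E{j + 1}" for j in range(n_vars)]
    return (
        pd.DataFrame(X, index=ids, columns=cols),
        pd.Series(y, index=ids, name="response"),
        {"scores": np.column_stack([s1, s2]), "loadings": q},
    )


def paper_compounds() -> pd.DataFrame:
    """Fixture table of the 13 quinuclidine carbamates.

    Columns: id, name, formula_printed (empty where the source gives none),
    formula_name_derived, smiles (cation for quaternary salts), counterion,
    quaternized, smiles_inferred (1 where the structure was inferred from
    the naming conventions rather than a printed formula).
    """
    path = resources.files("quincarb.data").joinpath("compounds.csv")
    with path.open() as fh:
        df = pd.read_csv(fh, dtype={"id": int}, keep_default_na=False)
    return df
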