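"""Synthetic PK-PD data with known ground truth.

Each component concentration follows a Bateman profile — the
one-compartment, first-order absorption/elimination curve
C(t) = A·(e^{-k_e t} − e^{-k_a t}) that rises to a single peak and
decays, matching the shape of the measured serum time courses.  The PD
response is a known signed combination of the standardized component
curves plus Gaussian noise, so attribution methods can be scored
against the true effect signs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .dataio import COMPONENTS, ENDPOINTS, PKPDDataset

__all__ = [
    "DEFAULT_TIMES",
    "SyntheticGroundTruth",
    "bateman_profile",
    "generate_pkpd",
    "make_ground_truth",
]

#: Sampling grid of the bundled herb tables (hours).
DEFAULT_TIMES = np.array(
    [0.08, 0.25, 0.5, 0.75, 1.0, 2.0, 3.0, 4.0, 6.0, 8.0, 10.0, 12.0]
)


@dataclass
class SyntheticGroundTruth:
    """Generator parameters and the attribution answer key.

    ``pk_params`` holds one (A, k_a, k_e) triple per component with
    k_a > k_e > 0 (A is a dose/volume scale, rates are per hour).
    ``effect_signs``/``effect_sizes`` are K×E (component × endpoint);
    sign 0 forces size 0.  ``link`` selects how standardized
    concentrations enter the response: identity or the saturating
    z/(1+|z|).
    """

    component_names: list[str]
    endpoints: list[str]
    pk_params: np.ndarray  # K×3: A, k_a, k_e
    effect_signs: np.ndarray  # K×E in {-1, 0, +1}
    effect_sizes: np.ndarray  # K×E, >= 0
    noise_sd: float = 0.2
    link: str = "linear"
    seed: int = 0

    def __post_init__(self) -> None:
        self.pk_params = np.asarray(self.pk_params, dtype=float)
        self.effect_signs = np.asarray(self.effect_signs)
        self.effect_sizes = np.asarray(self.effect_sizes, dtype=float)
        k = len(self.component_names)
        e = len(self.endpoints)
        if self.pk_params.shape != (k, 3):
            raise ValueError(f"pk_params must be {k}×3")
        if self.effect_signs.shape != (k, e) or self.effect_sizes.shape != (k, e):
            raise ValueError(f"effect arrays must be {k}×{e}")
        ka, ke = self.pk_params[:, 1], self.pk_params[:, 2]
        if np.any(ke <= 0) or np.any(ka <= ke):
            raise ValueError("require k_a > k_e > 0 for every component")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if np.any((self.effect_signs == 0) & (self.effect_sizes != 0)):
            raise ValueError("components with sign 0 must have size 0")
        if self.link not in ("linear", "saturating"):
            raise ValueError(f"unknown link {self.link!r}")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "component_names": self.component_names,
                    "endpoints": self.endpoints,
                    "pk_params": self.pk_params.tolist(),
                    "effect_signs": self.effect_signs.tolist(),
                    "effect_sizes": self.effect_sizes.tolist(),
                    "noise_sd": self.noise_sd,
                    "link": self.link,
                    "seed": self.seed,
                },
                indent=1,
            )
        )


def bateman_profile(
    A: float, k_a: float, k_e: float, times: np.ndarray
) -> np.ndarray:
    """One-compartment oral-absorption curve A·(e^{-k_e t} − e^{-k_a t}).

    Non-negative for t ≥ 0, zero at t → 0⁺, single interior maximum at
    t_max = ln(k_a/k_e)/(k_a − k_e).
    """
    if not (k_a > k_e > 0):
        raise ValueError(f"require k_a > k_e > 0, got k_a={k_a}, k_e={k_e}")
    t = np.asarray(times, dtype=float)
    return A * (np.exp(-k_e * t) - np.exp(-k_a * t))


def make_ground_truth(
    seed: int = 0,
    n_components: int = 10,
    endpoints: list[str] | None = None,
    n_active: int = 2,
    effect_size: float = 1.0,
    noise_sd: float = 0.2,
    link: str = "linear",
    charcoal_like: bool = False,
) -> SyntheticGroundTruth:
    """Draw a random but reproducible ground truth at fixture scale.

    PK parameters are sampled so peak concentrations span roughly the
    two orders of magnitude seen in the real tables.  ``n_active``
    components per endpoint get a random ±1 effect of ``effect_size``
    standardized units; the rest are inert.  The default of two active
    components per endpoint mirrors the herb setting, where a couple of
    dominant effective substances are expected to drive each marker.  ``charcoal_like`` zeroes
    the dose of one component, emulating a constituent destroyed by
    processing (the all-zero oxpaeoniflorin column of the charcoal
    table) to exercise the zero-variance path.
    """
    endpoints = list(endpoints) if endpoints is not None else list(ENDPOINTS)
    rng = np.random.default_rng(seed)
    names = (
        list(COMPONENTS[:n_components])
        if n_components <= len(COMPONENTS)
        else [f"comp_{i}" for i in range(n_components)]
    )
    # rates are drawn log-uniformly so peak times span roughly 0.1-6 h,
    # matching the kinetic diversity of the measured tables (whose
    # columns peak anywhere from 0.08 h to 6 h); tightly clustered
    # rates would make the columns nearly collinear, which the real
    # data is not
    A = 10.0 ** rng.uniform(0.5, 2.5, size=n_components)
    k_e = 10.0 ** rng.uniform(np.log10(0.04), np.log10(1.2), size=n_components)
    ratio = 10.0 ** rng.uniform(np.log10(3.0), np.log10(100.0), size=n_components)
    k_a = k_e * ratio
    pk = np.column_stack([A, k_a, k_e])
    zero_idx = None
    if charcoal_like:
        zero_idx = int(rng.integers(n_components))
        pk[zero_idx, 0] = 0.0
    signs = np.zeros((n_components, len(endpoints)), dtype=int)
    sizes = np.zeros((n_components, len(endpoints)))
    for e in range(len(endpoints)):
        candidates = [i for i in range(n_components) if i != zero_idx]
        active = rng.choice(candidates, size=min(n_active, len(candidates)), replace=False)
        signs[active, e] = rng.choice([-1, 1], size=len(active))
        sizes[active, e] = effect_size
    return SyntheticGroundTruth(
        component_names=names,
        endpoints=endpoints,
        pk_params=pk,
        effect_signs=signs,
        effect_sizes=sizes,
        noise_sd=noise_sd,
        link=link,
        seed=seed,
    )


def generate_pkpd(
    truth: SyntheticGroundTruth,
    times: np.ndarray | None = None,
    herb_label: str = "synthetic",
) -> tuple[PKPDDataset, SyntheticGroundTruth]:
    """Realize a dataset from a ground truth; reproducible by its seed.

    PD_t = Σ_k size_k·sign_k·g(z_tk) + ε_t with z the per-column
    standardized concentrations, g the chosen link and ε Gaussian noise.
    Constant (zero-dose) columns stay identically zero in z.
    """
    t = np.asarray(times, dtype=float) if times is not None else DEFAULT_TIMES.copy()
    rng = np.random.default_rng(truth.seed)
    K = len(truth.component_names)
    conc = np.column_stack(
        [bateman_profile(*truth.pk_params[k], t) for k in range(K)]
    )
    sd = conc.std(axis=0)
    z = (conc - conc.mean(axis=0)) / np.where(sd == 0, 1.0, sd)
    g = z if truth.link == "linear" else z / (1.0 + np.abs(z))
    pd_endpoints = {}
    for e, name in enumerate(truth.endpoints):
        signal = g @ (truth.effect_sizes[:, e] * truth.effect_signs[:, e])
        noise = rng.normal(0.0, truth.noise_sd, size=len(t))
        pd_endpoints[name] = signal + noise
    dataset = PKPDDataset(
        herb_label=herb_label,
        times=t,
        component_names=list(truth.component_names),
        concentrations=conc,
        pd_endpoints=pd_endpoints,
    )
    return dataset, truth
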