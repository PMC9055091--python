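"""Reading, writing and splitting PK-PD time-course tables.

A dataset couples the serum concentration time course of the measured
chemical components (PK side, μg/mL) with one or more pharmacodynamic
effect series (PD side, normalized percentages).  The bundled fixtures
are the twelve-point training tables for Moutan Cortex (MC) and Moutan
Cortex charcoal (MCC), each with ten components and the two endpoints
TXB2 (thromboxane B2, pro-coagulant marker) and 6-keto-PGF1α
(prostacyclin metabolite, anti-coagulant marker).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: Component columns in the order of the bundled tables; attribution
#: tables are emitted in this order.
COMPONENTS = [
    "gallic_acid",
    "5_HMF",
    "3_H_2_M_4_P",
    "oxpaeoniflorin",
    "3_8_D_2_MC",
    "paeoniflorin",
    "benzoic_acid",
    "methyl_paraben",
    "quercetin",
    "paeonol",
]

#: PD endpoint columns of the bundled tables.
ENDPOINTS = ["TXB2", "6_keto_PGF1a"]

TIME_COLUMN = "time_h"

HERB_FIXTURES = {"mc": "mc_training.csv", "mcc": "mcc_training.csv"}


class SchemaError(ValueError):
    """A required column is missing from the input table."""


class ParseError(ValueError):
    """A cell could not be parsed as a number."""


class ValidationError(ValueError):
    """The parsed table violates a dataset invariant."""


@dataclass
class PKPDDataset:
    """One herb's time-indexed concentration matrix plus PD endpoint vectors.

    Attributes
    ----------
    herb_label : str
        Free-text label (e.g. ``"mc"``).
    times : np.ndarray
        Sampling times in hours, strictly increasing, all positive.
    component_names : list[str]
        Names of the K concentration columns, order preserved.
    concentrations : np.ndarray
        N×K matrix of serum concentrations (μg/mL), non-negative.
    pd_endpoints : dict[str, np.ndarray]
        Endpoint name → length-N effect vector (percent, may be negative).
    """

    herb_label: str
    times: np.ndarray
    component_names: list[str]
    concentrations: np.ndarray
    pd_endpoints: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.pd_endpoints = {
            k: np.asarray(v, dtype=float) for k, v in self.pd_endpoints.items()
        }
        self.validate()

    # -- invariants ----------------------------------------------------
    def validate(self) -> None:
        n, k = self.concentrations.shape
        if self.times.ndim != 1 or len(self.times) != n:
            raise ValidationError(
                f"times has length {len(self.times)}, expected {n}"
            )
        if len(self.component_names) != k:
            raise ValidationError(
                f"{len(self.component_names)} component names for {k} columns"
            )
        if not np.all(np.isfinite(self.concentrations)):
            raise ValidationError("concentrations contain non-finite values")
        if np.any(self.concentrations < 0):
            raise ValidationError("concentrations must be non-negative")
        if np.any(self.times <= 0):
            raise ValidationError("times must all be > 0")
        if np.any(np.diff(self.times) <= 0):
            raise ValidationError("times must be strictly increasing")
        for name, vec in self.pd_endpoints.items():
            if vec.shape != (n,):
                raise ValidationError(
                    f"endpoint {name!r} has length {len(vec)}, expected {n}"
                )
            if not np.all(np.isfinite(vec)):
                raise ValidationError(f"endpoint {name!r} has non-finite values")

    # -- convenience ---------------------------------------------------
    @property
    def n_times(self) -> int:
        return len(self.times)

    @property
    def n_components(self) -> int:
        return len(self.component_names)

    def endpoint(self, name: str) -> np.ndarray:
        try:
            return self.pd_endpoints[name]
        except KeyError:
            raise KeyError(
                f"unknown endpoint {name!r}; have {sorted(self.pd_endpoints)}"
            ) from None

    def subset(self, rows: np.ndarray | list[int], label_suffix: str = "") -> "PKPDDataset":
        """Row subset preserving chronological order."""
        rows = np.sort(np.asarray(rows, dtype=int))
        return PKPDDataset(
            herb_label=self.herb_label + label_suffix,
            times=self.times[rows],
            component_names=list(self.component_names),
            concentrations=self.concentrations[rows],
            pd_endpoints={k: v[rows] for k, v in self.pd_endpoints.items()},
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.concentrations, columns=self.component_names)
        df.insert(0, TIME_COLUMN, self.times)
        for name, vec in self.pd_endpoints.items():
            df[name] = vec
        return df


def load_pkpd_table(
    path: str | Path,
    *,
    herb_label: str | None = None,
    time_column: str = TIME_COLUMN,
    endpoint_columns: list[str] | None = None,
    component_columns: list[str] | None = None,
) -> PKPDDataset:
    """Read a CSV time-course table into a :class:`PKPDDataset`.

    Column mapping: ``time_column`` names the sampling-time column;
    ``endpoint_columns`` (default: any of the bundled endpoint names
    present) name the PD columns; every remaining column is a component,
    unless ``component_columns`` pins them explicitly.  Component order
    is preserved as given in the file (or the explicit list).
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    if endpoint_columns is None:
        endpoint_columns = [c for c in df.columns if c in ENDPOINTS]
    for col in [time_column, *endpoint_columns, *(component_columns or [])]:
        if col not in df.columns:
            raise SchemaError(f"column {col!r} missing from {path.name}")
    if component_columns is None:
        component_columns = [
            c for c in df.columns if c != time_column and c not in endpoint_columns
        ]
    if not component_columns:
        raise SchemaError(f"no component columns found in {path.name}")

    def numeric(col: str) -> np.ndarray:
        out = np.empty(len(df), dtype=float)
        for i, raw in enumerate(df[col]):
            try:
                out[i] = float(raw)
            except (TypeError, ValueError):
                raise ParseError(
                    f"{path.name}: non-numeric value {raw!r} at row {i}, "
                    f"column {col!r}"
                ) from None
        return out

    times = numeric(time_column)
    if len(np.unique(times)) != len(times):
        raise ValidationError(f"{path.name}: duplicate time values")
    conc = np.column_stack([numeric(c) for c in component_columns])
    endpoints = {c: numeric(c) for c in endpoint_columns}
    return PKPDDataset(
        herb_label=herb_label or path.stem,
        times=times,
        component_names=list(component_columns),
        concentrations=conc,
        pd_endpoints=endpoints,
    )


def save_pkpd_table(dataset: PKPDDataset, path: str | Path) -> None:
    """Write a dataset back to CSV (inverse of :func:`load_pkpd_table`)."""
    dataset.to_frame().to_csv(path, index=False)


def load_fixture(herb: str) -> PKPDDataset:
    """Load a bundled training table by herb key (``"mc"`` or ``"mcc"``)."""
    key = herb.lower()
    if key not in HERB_FIXTURES:
        raise KeyError(f"unknown herb {herb!r}; expected one of {sorted(HERB_FIXTURES)}")
    ref = importlib.resources.files("pkpdsvr.data") / HERB_FIXTURES[key]
    with importlib.resources.as_file(ref) as p:
        return load_pkpd_table(p, herb_label=key)


def compute_pd_percent(c_treated: float, c_model: float, c_black: float) -> float:
    """Normalize a raw PD concentration to a percent effect.

    The effect of treatment is expressed relative to the span between the
    untreated disease-model animal and the blank control:
    ``(C_treated - C_model) / (C_model - C_black) * 100``.
    """
    denom = c_model - c_black
    if denom == 0:
        raise ZeroDivisionError(
            "model and blank control concentrations coincide; percent undefined"
        )
    return (c_treated - c_model) / denom * 100.0


def split_train_test(
    dataset: PKPDDataset, test_fraction: float = 1 / 6, seed: int = 0
) -> tuple[PKPDDataset, PKPDDataset]:
    """Random disjoint row split; test size = round(N·fraction), at least 1.

    Deterministic for a fixed seed.  Row order within each part stays
    chronological.
    """
    n = dataset.n_times
    if n < 2:
        raise ValidationError("need at least 2 rows to split")
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    n_test = max(1, int(round(n * test_fraction)))
    if n_test >= n:
        raise ValidationError("test fraction leaves no training rows")
    rng = np.random.default_rng(seed)
    test_idx = rng.choice(n, size=n_test, replace=False)
    mask = np.zeros(n, dtype=bool)
    mask[test_idx] = True
    train = dataset.subset(np.flatnonzero(~mask), "/train")
    test = dataset.subset(np.flatnonzero(mask), "/test")
    return train, test
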