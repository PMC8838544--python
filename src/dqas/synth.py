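"""Seeded synthetic survey tables and panelist rating sheets.

Everything the toolkit consumes can be generated here with controlled
statistical structure, so the full pipeline is testable without any real
export. Missing cells are independent Bernoulli(``missing_rate``) draws;
duplicates are injected by replacing the last ``floor(duplicate_rate * n)``
rows with uniform draws from the earlier rows, which makes the expected
duplicate ratio analytically known. Panel sheets draw integer-rounded
Gaussian noise around a per-metric latent quality on the 1-7 Likert scale.

Each generator takes its own seed; there is no global random state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .delphi import CRITERIA, LIKERT_MAX, LIKERT_MIN, Rating
from .metrics import DataTable

__all__ = ["TableSpec", "PanelSpec", "GeneratedTable", "generate_table", "generate_panel"]


@dataclass(frozen=True)
class TableSpec:
    """Shape and corruption parameters of a synthetic export."""

    n_rows: int
    n_vars: int
    missing_rate: float = 0.0
    duplicate_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_vars < 1:
            raise ValueError("table needs at least one row and one variable")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must be in [0, 1)")
        if not (0.0 <= self.duplicate_rate < 1.0):
            raise ValueError("duplicate_rate must be in [0, 1)")
        if self.duplicate_rate > 0.0 and self.n_rows < 2:
            raise ValueError("duplication requires at least two rows")


@dataclass(frozen=True)
class GeneratedTable:
    """A synthetic table plus its realized corruption counts."""

    table: DataTable
    n_missing_cells: int
    n_duplicate_rows: int


@dataclass(frozen=True)
class PanelSpec:
    """Panel size and rating-noise parameters for synthetic Delphi sheets."""

    n_panelists: int
    n_metrics: int
    latent_quality: tuple[float, ...] | None = None  # per metric, in [1, 7]
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_panelists < 1 or self.n_metrics < 1:
            raise ValueError("panel needs at least one panelist and one metric")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.latent_quality is not None:
            if len(self.latent_quality) != self.n_metrics:
                raise ValueError("latent_quality length must equal n_metrics")
            if any(not (LIKERT_MIN <= q <= LIKERT_MAX) for q in self.latent_quality):
                raise ValueError("latent qualities must lie on the Likert scale")


def generate_table(spec: TableSpec) -> GeneratedTable:
    """Deterministically generate a table per the spec's seed.

    Base cells are short tokens ``r<row>c<col>`` so rows start distinct.
    Missingness is applied cell-wise first; the last
    ``floor(duplicate_rate * n_rows)`` rows are then replaced by uniform
    draws from the earlier rows, missing pattern included, so injected
    duplicates are exact copies whatever the missing rate.
    """
    rng = np.random.default_rng(spec.seed)
    variables = tuple(f"v{j}" for j in range(spec.n_vars))
    cells = np.array(
        [[f"r{i}c{j}" for j in range(spec.n_vars)] for i in range(spec.n_rows)],
        dtype=object,
    )
    mask = rng.random(cells.shape) < spec.missing_rate
    cells[mask] = ""
    n_dup = int(np.floor(spec.duplicate_rate * spec.n_rows))
    if n_dup > 0:
        sources = rng.integers(0, spec.n_rows - n_dup, size=n_dup)
        for k, src in enumerate(sources):
            dest = spec.n_rows - n_dup + k
            cells[dest, :] = cells[src, :]
            mask[dest, :] = mask[src, :]
    table = DataTable.from_records(variables, cells.tolist())
    return GeneratedTable(
        table=table,
        n_missing_cells=int(mask.sum()),
        n_duplicate_rows=n_dup,
    )


def generate_panel(spec: PanelSpec) -> list[Rating]:
    """Deterministically generate a complete rating sheet per the spec.

    Every (panelist, metric) pair carries all four criterion ratings;
    each rating is the metric's latent quality plus Gaussian noise, rounded
    and clipped to the 1-7 scale.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.latent_quality is None:
        latent = rng.uniform(LIKERT_MIN, LIKERT_MAX, size=spec.n_metrics)
    else:
        latent = np.asarray(spec.latent_quality, dtype=float)
    ratings: list[Rating] = []
    for p in range(spec.n_panelists):
        for m in range(spec.n_metrics):
            noise = rng.normal(0.0, spec.noise_sd, size=len(CRITERIA))
            values = np.clip(np.rint(latent[m] + noise), LIKERT_MIN, LIKERT_MAX)
            for criterion, value in zip(CRITERIA, values):
                ratings.append(
                    Rating(
                        panelist_id=f"panelist{p}",
                        metric_id=f"metric{m}",
                        criterion=criterion,
                        value=int(value),
                    )
                )
    return ratings
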