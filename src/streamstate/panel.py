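"""Occurrence panels, functional-trait tables, and posterior summaries.

The central container is :class:`OccurrencePanel`, a dense binary tensor of
genus x series x occasion presence/absence records from a space-state
colonization experiment.  A *series* is one row of artificial substrates in
one stream under one disturbance-intensity battery; its successive columns
(destructively sampled on different days) form a single time series.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FREQUENCY_LEVELS",
    "TREATMENT_CELLS",
    "HYPOTHESIS_BANDS",
    "OccurrencePanel",
    "TraitRecord",
    "CredibleSummary",
    "SchemaError",
    "DuplicateKeyError",
    "load_trait_table",
    "assign_group",
    "group_hypotheses",
    "credible_interval",
    "read_occurrence_table",
    "write_occurrence_table",
]

#: Disturbance-frequency rows: one control plus every-6-days (F1),
#: every-3-days (F2) and random-schedule (F3) treatments.
FREQUENCY_LEVELS = ("C", "F1", "F2", "F3")

#: The six intensity x frequency treatment cells, each with its own
#: permanence deviation.  I1/I2 are the 30 and 60 m3/h pump batteries.
TREATMENT_CELLS = ("I1F1", "I1F2", "I1F3", "I2F1", "I2F2", "I2F3")

#: Ordinal hypothesis bands for permanence/recolonization levels.
HYPOTHESIS_BANDS = {
    "low": (0.0, 0.33),
    "moderate": (0.33, 0.66),
    "high": (0.66, 1.0),
    "very high": (0.8, 1.0),
}

_REQUIRED_COLUMNS = ("genus", "stream", "frequency", "battery", "occasion", "occurrence")


class SchemaError(ValueError):
    """An input table is missing required columns or levels."""


class DuplicateKeyError(ValueError):
    """Two rows share the same (genus, series, occasion) key."""


@dataclass(frozen=True)
class TraitRecord:
    """One taxon's functional traits and life-history strategy group.

    Taxa resolved only to family level are treated as genus-level rows.
    The hypothesis levels state the expected band of the permanence (psi)
    and recolonization (theta) probabilities for the taxon's group.
    """

    genus: str
    group: int
    body_shape: str
    fixation: str
    cycle_length: str
    reproductive_cycles: str
    psi_hypothesis: str
    theta_hypothesis: str

    def __post_init__(self) -> None:
        if not 1 <= self.group <= 9:
            raise ValueError(f"group id must be 1..9, got {self.group}")
        for level in (self.psi_hypothesis, self.theta_hypothesis):
            if level not in HYPOTHESIS_BANDS:
                raise ValueError(f"unknown hypothesis level {level!r}")


@dataclass(frozen=True)
class CredibleSummary:
    """Equal-tailed credible interval plus mean/median of a posterior margin."""

    mean: float
    median: float
    lower: float
    upper: float
    level: float = 0.95

    def __post_init__(self) -> None:
        if not 0 < self.level < 1:
            raise ValueError("level must be in (0, 1)")
        if not self.lower <= self.median <= self.upper:
            raise ValueError("requires lower <= median <= upper")

    def overlaps(self, other: "CredibleSummary") -> bool:
        """Closed-interval overlap with another summary at the same level."""
        if abs(self.level - other.level) > 1e-12:
            raise ValueError("cannot compare intervals at different levels")
        return self.lower <= other.upper and other.lower <= self.upper


def credible_interval(draws: Sequence[float], level: float = 0.95) -> CredibleSummary:
    """Equal-tailed credible interval from posterior draws.

    Uses linear-interpolation empirical quantiles at ``(1 - level) / 2`` and
    ``1 - (1 - level) / 2``.
    """
    arr = np.asarray(draws, dtype=float).ravel()
    if arr.size < 2:
        raise ValueError("need at least two draws")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    tail = (1.0 - level) / 2.0
    lower, upper = np.quantile(arr, [tail, 1.0 - tail])
    return CredibleSummary(
        mean=float(arr.mean()),
        median=float(np.median(arr)),
        lower=float(lower),
        upper=float(upper),
        level=level,
    )


# ---------------------------------------------------------------------------
# Trait table


def load_trait_table(path: str | None = None) -> list[TraitRecord]:
    """Load the packaged (or a user-supplied) taxon -> trait-group table."""
    if path is None:
        with resources.files("streamstate.data").joinpath("trait_groups.csv").open() as fh:
            df = pd.read_csv(fh)
    else:
        df = pd.read_csv(path)
    records = []
    for row in df.itertuples(index=False):
        records.append(
            TraitRecord(
                genus=str(row.taxon),
                group=int(row.group),
                body_shape=str(row.body_shape),
                fixation=str(row.fixation),
                cycle_length=str(row.cycle_length),
                reproductive_cycles=str(row.reproductive_cycles),
                psi_hypothesis=str(row.psi_hypothesis),
                theta_hypothesis=str(row.theta_hypothesis),
            )
        )
    return records


def assign_group(trait_table: Sequence[TraitRecord], genus: str) -> int:
    """Return the life-history strategy group (1-9) of a taxon."""
    for rec in trait_table:
        if rec.genus == genus:
            return rec.group
    raise KeyError(f"taxon {genus!r} not present in the trait table")


def group_hypotheses(trait_table: Sequence[TraitRecord]) -> dict[int, tuple[str, str]]:
    """Map group id -> (psi hypothesis level, theta hypothesis level)."""
    out: dict[int, tuple[str, str]] = {}
    for rec in trait_table:
        levels = (rec.psi_hypothesis, rec.theta_hypothesis)
        if out.setdefault(rec.group, levels) != levels:
            raise ValueError(f"inconsistent hypothesis levels within group {rec.group}")
    return out


# ---------------------------------------------------------------------------
# Occurrence panel


@dataclass
class OccurrencePanel:
    """Dense binary occurrence tensor indexed (genus, series, occasion).

    Parameters
    ----------
    occurrences
        int array of shape (n_genera, n_series, n_occasions) with values in
        {0, 1}.
    genera
        Genus (or family) name per tensor row.
    series_meta
        One row per series with columns ``stream``, ``frequency`` (C/F1/F2/F3)
        and ``battery`` (1 or 2).
    occasion_days
        Calendar day of each sampling occasion; metadata only, the transition
        model is indexed by occasion step.
    genus_group
        Genus name -> functional group id (1-9).
    """

    occurrences: np.ndarray
    genera: list[str]
    series_meta: pd.DataFrame
    occasion_days: np.ndarray
    genus_group: dict[str, int]

    def __post_init__(self) -> None:
        self.occurrences = np.asarray(self.occurrences)
        self.occasion_days = np.asarray(self.occasion_days, dtype=int)
        if self.occurrences.ndim != 3:
            raise ValueError("occurrences must be 3-dimensional")
        n_g, n_s, n_t = self.occurrences.shape
        if len(self.genera) != n_g:
            raise ValueError("genera length mismatch")
        if len(self.series_meta) != n_s:
            raise ValueError("series_meta length mismatch")
        if self.occasion_days.size != n_t:
            raise ValueError("occasion_days length mismatch")
        if not np.isin(self.occurrences, (0, 1)).all():
            raise ValueError("occurrence values must be 0 or 1")
        if n_t > 1 and not (np.diff(self.occasion_days) > 0).all():
            raise ValueError("occasion_days must be strictly increasing")
        missing = [g for g in self.genera if g not in self.genus_group]
        if missing:
            raise ValueError(f"genera without a group id: {missing}")
        bad = {g: i for g, i in self.genus_group.items() if not 1 <= int(i) <= 9}
        if bad:
            raise ValueError(f"group ids outside 1..9: {bad}")

    # -- basic accessors ----------------------------------------------------

    @property
    def n_genera(self) -> int:
        return self.occurrences.shape[0]

    @property
    def n_series(self) -> int:
        return self.occurrences.shape[1]

    @property
    def n_occasions(self) -> int:
        return self.occurrences.shape[2]

    def series_cells(self) -> np.ndarray:
        """Treatment-cell label per series: 'C' or one of the six IxFy cells."""
        freq = self.series_meta["frequency"].to_numpy()
        batt = self.series_meta["battery"].to_numpy()
        labels = np.where(
            freq == "C", "C", np.char.add(np.char.add("I", batt.astype(str)), freq.astype(str))
        )
        return labels.astype(object)

    def all_zero_genera(self) -> list[str]:
        """Genera never observed anywhere in the panel."""
        mask = self.occurrences.sum(axis=(1, 2)) == 0
        return [g for g, m in zip(self.genera, mask) if m]

    def select_series(self, mask: np.ndarray) -> "OccurrencePanel":
        return OccurrencePanel(
            occurrences=self.occurrences[:, mask, :],
            genera=list(self.genera),
            series_meta=self.series_meta.loc[mask].reset_index(drop=True),
            occasion_days=self.occasion_days.copy(),
            genus_group=dict(self.genus_group),
        )

    def control_only(self) -> "OccurrencePanel":
        """Sub-panel with only the undisturbed control series."""
        return self.select_series((self.series_meta["frequency"] == "C").to_numpy())

    # -- IO -----------------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        """Long-format table with one row per genus x series x occasion."""
        n_g, n_s, n_t = self.occurrences.shape
        gi, si, ti = np.meshgrid(range(n_g), range(n_s), range(n_t), indexing="ij")
        meta = self.series_meta.iloc[si.ravel()]
        return pd.DataFrame(
            {
                "genus": np.asarray(self.genera, dtype=object)[gi.ravel()],
                "stream": meta["stream"].to_numpy(),
                "frequency": meta["frequency"].to_numpy(),
                "battery": meta["battery"].to_numpy(),
                "occasion": ti.ravel() + 1,
                "occurrence": self.occurrences[gi.ravel(), si.ravel(), ti.ravel()],
            }
        )


def write_occurrence_table(panel: OccurrencePanel, path: str, format: str = "csv") -> None:
    """Write a panel to a long-format CSV/TSV occurrence table."""
    sep = {"csv": ",", "tsv": "\t"}[format]
    panel.to_frame().to_csv(path, sep=sep, index=False)


def read_occurrence_table(
    path: str,
    format: str = "csv",
    genus_group: Mapping[str, int] | None = None,
    occasion_days: Sequence[int] | None = None,
) -> OccurrencePanel:
    """Read a long-format occurrence table into a dense panel.

    The table needs the columns ``genus, stream, frequency, battery,
    occasion, occurrence``.  Missing (genus, series, occasion) combinations
    are filled with 0; duplicated combinations are an error.  If
    ``genus_group`` is not given, groups are looked up in the packaged trait
    table.  Genera never observed at all are kept but reported via a warning
    so baseline fits can decide what to do with them.
    """
    sep = {"csv": ",", "tsv": "\t"}[format]
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required columns: {missing}")
    if not np.isin(df["occurrence"].to_numpy(), (0, 1)).all():
        raise ValueError("occurrence column must contain only 0 or 1")
    bad_freq = set(df["frequency"].astype(str)) - set(FREQUENCY_LEVELS)
    if bad_freq:
        raise SchemaError(f"unknown frequency levels: {sorted(bad_freq)}")

    key_cols = ["genus", "stream", "frequency", "battery", "occasion"]
    if df.duplicated(subset=key_cols).any():
        dupes = df[df.duplicated(subset=key_cols, keep=False)]
        raise DuplicateKeyError(
            f"duplicate (genus, series, occasion) rows:\n{dupes.head()}"
        )

    genera = sorted(df["genus"].astype(str).unique())
    series_meta = (
        df[["stream", "frequency", "battery"]]
        .drop_duplicates()
        .sort_values(["stream", "frequency", "battery"])
        .reset_index(drop=True)
    )
    occasions = np.sort(df["occasion"].unique())

    g_idx = {g: i for i, g in enumerate(genera)}
    s_idx = {
        (r.stream, r.frequency, r.battery): i
        for i, r in enumerate(series_meta.itertuples(index=False))
    }
    t_idx = {t: i for i, t in enumerate(occasions)}

    occ = np.zeros((len(genera), len(series_meta), len(occasions)), dtype=np.int8)
    for row in df.itertuples(index=False):
        occ[
            g_idx[str(row.genus)],
            s_idx[(row.stream, row.frequency, row.battery)],
            t_idx[row.occasion],
        ] = int(row.occurrence)

    if genus_group is None:
        table = load_trait_table()
        genus_group = {g: assign_group(table, g) for g in genera}
    else:
        genus_group = dict(genus_group)

    if occasion_days is None:
        occasion_days = occasions
    panel = OccurrencePanel(
        occurrences=occ,
        genera=genera,
        series_meta=series_meta,
        occasion_days=np.asarray(occasion_days),
        genus_group=genus_group,
    )
    zeros = panel.all_zero_genera()
    if zeros:
        warnings.warn(f"genera with no occurrences anywhere: {zeros}", stacklevel=2)
    return panel
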