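"""Container for experimental / synthetic observation tables.

An :class:`ObservationSet` wraps a tidy DataFrame of time-stamped
measurements of several kinds (gastric mass, gastric fraction of initial,
chyme viscosity, half-times) for one or more experiments, plus the
per-experiment metadata the fitting objectives need (initial viscosity
``mu0`` [Pa s], initial liquid load ``liq0`` [g], measured half-time [s]).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParseError

GASTRIC_MASS = "gastric_mass"
GASTRIC_FRACTION = "gastric_fraction"
VISCOSITY = "viscosity"
HALF_TIME = "half_time"

KINDS = (GASTRIC_MASS, GASTRIC_FRACTION, VISCOSITY, HALF_TIME)

_REQUIRED_COLUMNS = ("time_s", "value", "kind")


@dataclass
class ObservationSet:
    """Validated observation table.

    ``frame`` columns: ``experiment`` (str), ``time_s``, ``value``,
    ``kind`` and optionally ``sd`` (replicate standard deviation, same
    unit as ``value``).  ``meta`` maps experiment id to a dict that may
    hold ``mu0`` [Pa s], ``liq0`` [g], ``half_time_s`` [s], ``StomN0``
    [g] and free-form provenance.
    """

    frame: pd.DataFrame
    meta: dict[str, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        df = self.frame.copy()
        for col in _REQUIRED_COLUMNS:
            if col not in df.columns:
                raise ParseError(f"missing required column '{col}'")
        if "experiment" not in df.columns:
            df["experiment"] = "exp0"
        if "sd" not in df.columns:
            df["sd"] = np.nan
        bad_kind = ~df["kind"].isin(KINDS)
        if bad_kind.any():
            row = int(df.index[bad_kind][0])
            raise ParseError(
                f"row {row}: unknown kind '{df.loc[row, 'kind']}', "
                f"expected one of {KINDS}"
            )
        if (df["value"] < 0).any():
            row = int(df.index[df["value"] < 0][0])
            raise ParseError(f"row {row}: negative value")
        for (exp, kind), grp in df.groupby(["experiment", "kind"]):
            t = grp["time_s"].to_numpy()
            if np.any(np.diff(t) <= 0):
                i = int(np.argmax(np.diff(t) <= 0))
                raise ParseError(
                    f"times not strictly increasing for experiment "
                    f"'{exp}', kind '{kind}' (row {grp.index[i + 1]})"
                )
        self.frame = df.reset_index(drop=True)

    # -- convenience accessors --------------------------------------------

    @property
    def experiments(self) -> list[str]:
        return list(dict.fromkeys(self.frame["experiment"]))

    def series(self, kind: str, experiment: str | None = None
               ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(times_s, values, sds) for one kind of one experiment."""
        exp = experiment if experiment is not None else self.experiments[0]
        sel = self.frame[
            (self.frame["experiment"] == exp) & (self.frame["kind"] == kind)
        ]
        return (
            sel["time_s"].to_numpy(float),
            sel["value"].to_numpy(float),
            sel["sd"].to_numpy(float),
        )

    def n_points(self, kind: str | None = None) -> int:
        if kind is None:
            return len(self.frame)
        return int((self.frame["kind"] == kind).sum())

    def with_values(self, values: np.ndarray) -> "ObservationSet":
        """Copy with the ``value`` column replaced (used by noise
        injection); lengths must match."""
        if len(values) != len(self.frame):
            raise ValueError("values length mismatch")
        df = self.frame.copy()
        df["value"] = np.asarray(values, dtype=float)
        return ObservationSet(df, dict(self.meta))
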