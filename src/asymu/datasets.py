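"""Validation-study data containers and the packaged example studies.

A validation study is a factorial design: ``n`` blocks (factor-level
combinations, e.g. weeks), each measured at ``m`` known concentration levels
with ``p`` replicates, varying ``q`` two-level (or multi-level) factors across
blocks.  Data are stored long-format, one row per measurement; the wide layout
with one column per concentration level (as such studies are usually printed)
is accepted and emitted as well.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .profiles import BLOCK, REPEATABILITY, TermVariance, VarianceComponents

__all__ = [
    "ValidationStudy",
    "load_fixture",
    "load_reference_components",
    "FIXTURE_NAMES",
]

LONG_COLUMNS = ("block", "known_x", "replicate", "y")

FIXTURE_NAMES = ("thiamphenicol_milk", "clopidol_egg")

_FIXTURE_FACTORS = {
    "thiamphenicol_milk": ["Batch", "Storage", "Technician", "Mixer"],
    "clopidol_egg": ["Breeding", "Operator", "HPLC", "Extract storage"],
}
_FIXTURE_UNITS = {"thiamphenicol_milk": "μg/kg", "clopidol_egg": "μg/kg"}

# Published variance-component estimates for the two example studies
# (constant part in units^2, proportional part dimensionless).
_REFERENCE_COMPONENTS = {
    "thiamphenicol_milk": {
        REPEATABILITY: (0.90760, 0.00000),
        BLOCK: (0.88789, 0.00000),
        "Batch": (0.00000, 0.00004),
        "Storage": (1.06201, 0.00000),
        "Technician": (1.52630, 0.00000),
        "Mixer": (0.00000, 0.00029),
    },
    "clopidol_egg": {
        REPEATABILITY: (0.00000, 0.01096),
        BLOCK: (0.00142, 0.00524),
        "Breeding": (0.00118, 0.00048),
        "Operator": (0.00749, 0.00447),
        "HPLC": (0.00000, 0.00000),
        "Extract storage": (0.00258, 0.00000),
    },
}


@dataclass
class ValidationStudy:
    """Long-format records of an in-house validation study.

    Parameters
    ----------
    data : pandas.DataFrame
        One row per measurement with columns ``block``, one column per design
        factor, ``known_x`` (> 0, study units), ``replicate`` (1-based int) and
        ``y`` (measured concentration, study units).
    factors : list of str
        Names of the design-factor columns.
    units : str
        Free-text concentration units, carried through unchanged.
    """

    data: pd.DataFrame
    factors: list[str] = field(default_factory=list)
    units: str = ""

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in (*LONG_COLUMNS, *self.factors) if c not in df.columns]
        if missing:
            raise ValueError(f"validation data is missing columns: {missing}")
        if len(df) == 0:
            raise ValueError("no records")
        df = df.copy()
        df["known_x"] = pd.to_numeric(df["known_x"])
        df["y"] = pd.to_numeric(df["y"])
        df["replicate"] = df["replicate"].astype(int)
        if (df["known_x"] <= 0).any():
            bad = df.loc[df["known_x"] <= 0, "known_x"].unique()
            raise ValueError(f"known concentrations must be > 0, got {bad}")
        if not np.isfinite(df["y"]).all():
            raise ValueError("non-numeric or non-finite measurement results")
        keys = df[["block", "known_x", "replicate"]]
        if keys.duplicated().any():
            dup = keys[keys.duplicated()].iloc[0].tolist()
            raise ValueError(f"duplicate (block, known_x, replicate) key: {dup}")
        # each block must carry exactly one factor-level combination
        if self.factors:
            combos = df.groupby("block", sort=False)[self.factors].nunique()
            bad = combos[(combos > 1).any(axis=1)]
            if len(bad):
                raise ValueError(
                    f"blocks map to multiple factor-level combinations: {list(bad.index)}"
                )
        self.data = df.reset_index(drop=True)

    # ---- design dimensions -------------------------------------------------
    @property
    def m(self) -> int:
        """Number of distinct known concentration levels."""
        return self.data["known_x"].nunique()

    @property
    def n(self) -> int:
        """Number of blocks (factor-level combinations)."""
        return self.data["block"].nunique()

    @property
    def p(self) -> int:
        """Replicates per (block, level)."""
        return int(self.data.groupby(["block", "known_x"]).size().max())

    @property
    def q(self) -> int:
        """Number of design factors."""
        return len(self.factors)

    @property
    def levels(self) -> np.ndarray:
        """Sorted distinct known concentrations."""
        return np.sort(self.data["known_x"].unique())

    def __len__(self) -> int:
        return len(self.data)

    # ---- construction ------------------------------------------------------
    @classmethod
    def from_long(
        cls,
        df: pd.DataFrame,
        factors: Sequence[str] = (),
        units: str = "",
        block: str = "block",
        known_x: str = "known_x",
        replicate: str = "replicate",
        y: str = "y",
    ) -> "ValidationStudy":
        """Build from a long-format frame, renaming columns as needed."""
        rename = {block: "block", known_x: "known_x", replicate: "replicate", y: "y"}
        missing = [c for c in rename if c not in df.columns]
        if missing:
            raise ValueError(f"validation data is missing columns: {missing}")
        return cls(df.rename(columns=rename), factors=list(factors), units=units)

    @classmethod
    def from_wide(
        cls,
        df: pd.DataFrame,
        factors: Sequence[str] = (),
        units: str = "",
        block: str = "block",
        level_columns: Sequence[str] | None = None,
    ) -> "ValidationStudy":
        """Build from the printed wide layout: one column per concentration level.

        ``level_columns`` defaults to every column (beyond block and factors)
        whose name parses as a positive number; the column name is the known
        concentration.  Replicates within a cell are not representable in the
        wide layout, so ``replicate`` is 1 throughout (p = 1 designs).
        """
        id_cols = [block, *factors]
        if level_columns is None:
            level_columns = []
            for c in df.columns:
                if c in id_cols:
                    continue
                try:
                    if float(c) > 0:
                        level_columns.append(c)
                except (TypeError, ValueError):
                    pass
        if not level_columns:
            raise ValueError("no concentration-level columns found in wide input")
        long = df.melt(
            id_vars=id_cols, value_vars=list(level_columns),
            var_name="known_x", value_name="y",
        )
        long = long.rename(columns={block: "block"})
        long["known_x"] = long["known_x"].astype(float)
        long["replicate"] = 1
        return cls(long, factors=list(factors), units=units)

    @classmethod
    def read_csv(
        cls,
        path,
        factors: Sequence[str] = (),
        units: str = "",
        layout: str = "auto",
        **col_names,
    ) -> "ValidationStudy":
        """Read a UTF-8 comma-separated file in long or wide ('as printed') layout.

        With ``layout='auto'`` the long layout is assumed when the canonical
        long columns are all present, otherwise wide.
        """
        df = pd.read_csv(path, dtype={"block": str, col_names.get("block", "block"): str})
        if len(df) == 0:
            raise ValueError(f"no records in {path}")
        if layout == "auto":
            blockcol = col_names.get("block", "block")
            have_long = all(
                col_names.get(c, c) in df.columns for c in ("known_x", "replicate", "y")
            )
            layout = "long" if have_long else "wide"
        if layout == "long":
            return cls.from_long(df, factors=factors, units=units, **col_names)
        if layout == "wide":
            return cls.from_wide(df, factors=factors, units=units,
                                 block=col_names.get("block", "block"))
        raise ValueError(f"unknown layout {layout!r}")

    # ---- export ------------------------------------------------------------
    def to_long(self) -> pd.DataFrame:
        cols = ["block", *self.factors, "known_x", "replicate", "y"]
        return self.data[cols].copy()

    def to_wide(self) -> pd.DataFrame:
        """Printed layout; requires p = 1."""
        if self.p != 1:
            raise ValueError("wide layout requires a single replicate per level")
        wide = self.data.pivot_table(
            index=["block", *self.factors], columns="known_x", values="y"
        ).reset_index()
        wide.columns = [
            f"{c:g}" if isinstance(c, float) else str(c) for c in wide.columns
        ]
        wide.columns.name = None
        return wide

    def write_csv(self, path, layout: str = "long") -> None:
        frame = self.to_long() if layout == "long" else self.to_wide()
        frame.to_csv(path, index=False)

    def value(self, block, known_x, replicate: int = 1) -> float:
        """Single measured value at a (block, level, replicate) key."""
        df = self.data
        sel = df[
            (df["block"] == str(block))
            & (df["known_x"] == float(known_x))
            & (df["replicate"] == int(replicate))
        ]
        if len(sel) != 1:
            raise KeyError((block, known_x, replicate))
        return float(sel["y"].iloc[0])


def load_fixture(name: str) -> ValidationStudy:
    """Load one of the packaged example studies.

    ``"thiamphenicol_milk"``: Thiamphenicol in milk, m=4 levels (25-100 μg/kg),
    n=8 blocks, p=1, factors milk batch / storage / technician / mixer.
    ``"clopidol_egg"``: Clopidol in egg, m=6 levels (0.2-6 μg/kg), n=8 blocks,
    p=1, factors breeding / operator / HPLC column batch / extract storage.
    """
    if name not in FIXTURE_NAMES:
        raise KeyError(f"unknown fixture {name!r}; available: {FIXTURE_NAMES}")
    ref = importlib.resources.files("asymu.data").joinpath(f"{name}.csv")
    with importlib.resources.as_file(ref) as path:
        df = pd.read_csv(path, dtype={"block": str})
    return ValidationStudy.from_wide(
        df, factors=_FIXTURE_FACTORS[name], units=_FIXTURE_UNITS[name]
    )


def load_reference_components(name: str) -> VarianceComponents:
    """Published variance-component estimates for a packaged example study.

    These are the reported constant/proportional estimates for the two example
    datasets, useful as inputs for precision tables and for cross-checking a
    fresh fit.
    """
    if name not in _REFERENCE_COMPONENTS:
        raise KeyError(f"unknown fixture {name!r}; available: {FIXTURE_NAMES}")
    return VarianceComponents(
        {k: TermVariance(*v) for k, v in _REFERENCE_COMPONENTS[name].items()}
    )
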