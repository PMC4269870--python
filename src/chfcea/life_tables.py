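"""Age- and sex-specific background (non-cardiovascular) mortality.

The cohort model treats non-CV death as a competing, treatment-independent
process driven by a national life table: rows of (age, sex, qx) where ``qx``
is the annual probability of death.  Within each year of age the annual
probability is converted to a constant monthly survival factor
``(1 - qx)**(1/12)`` and the cohort ages as cycles advance.

No real national table is bundled; :func:`make_synthetic_life_table` builds a
synthetic Gompertz–Makeham table of plausible southern-European magnitude
(see ``data/life_table_synthetic_greek.csv``) and users can point the config
at a real file.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "LifeTable",
    "read_life_table",
    "load_bundled_life_table",
    "make_synthetic_life_table",
    "monthly_noncv_survival",
]


class LifeTableError(ValueError):
    """Raised when a life-table file fails validation."""


@dataclass
class LifeTable:
    """Validated life table with contiguous ages per sex and qx in [0, 1]."""

    table: pd.DataFrame  # columns: age (int), sex ('m'/'f'), qx (float)
    _lookup: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        t = self.table
        required = {"age", "sex", "qx"}
        if not required.issubset(t.columns):
            raise LifeTableError(f"life table needs columns {sorted(required)}")
        if t.duplicated(subset=["age", "sex"]).any():
            raise LifeTableError("duplicate (age, sex) rows in life table")
        if not t["sex"].isin(["m", "f"]).all():
            raise LifeTableError("sex must be 'm' or 'f'")
        if ((t["qx"] < 0) | (t["qx"] > 1)).any():
            bad = t.loc[(t["qx"] < 0) | (t["qx"] > 1)]
            raise LifeTableError(f"qx outside [0, 1] at ages {bad['age'].tolist()}")
        self._lookup = {}
        for sex, grp in t.groupby("sex"):
            ages = np.sort(grp["age"].to_numpy())
            if not np.array_equal(ages, np.arange(ages.min(), ages.max() + 1)):
                raise LifeTableError(f"ages for sex '{sex}' are not contiguous")
            g = grp.sort_values("age")
            if g["qx"].iloc[-1] != 1.0:
                raise LifeTableError(f"terminal age for sex '{sex}' must have qx=1")
            self._lookup[sex] = (
                int(g["age"].iloc[0]),
                int(g["age"].iloc[-1]),
                g["qx"].to_numpy(float),
            )

    @property
    def min_age(self) -> int:
        return min(v[0] for v in self._lookup.values())

    @property
    def max_age(self) -> int:
        return max(v[1] for v in self._lookup.values())

    def qx(self, age: int, sex: str) -> float:
        """Annual death probability at integer ``age`` for ``sex``."""
        lo, hi, q = self._lookup[sex]
        if age < lo or age > hi:
            raise LifeTableError(f"age {age} outside life-table range [{lo}, {hi}]")
        return float(q[age - lo])

    def annual_qx_path(self, age0: float, n_years: int, sex: str) -> np.ndarray:
        ages = (int(age0) + np.arange(n_years)).clip(max=self._lookup[sex][1])
        lo = self._lookup[sex][0]
        if int(age0) < lo:
            raise LifeTableError(f"starting age {age0} below life-table minimum {lo}")
        return self._lookup[sex][2][ages - lo]


def read_life_table(path) -> LifeTable:
    """Read a delimited life table with header ``age,sex,qx``."""
    df = pd.read_csv(path)
    try:
        df["age"] = df["age"].astype(int)
        df["qx"] = df["qx"].astype(float)
    except (KeyError, ValueError) as exc:
        raise LifeTableError(f"malformed life table {path}: {exc}") from exc
    return LifeTable(df)


def make_synthetic_life_table(
    makeham_a: float = 2.0e-4,
    gompertz_b_male: float = 5.0e-5,
    gompertz_b_female: float = 2.8e-5,
    gompertz_c: float = 1.094,
    max_age: int = 100,
) -> LifeTable:
    """Synthetic all-cause life table from a Gompertz–Makeham hazard.

    mu(age) = a + b * c**age, with sex entering through the senescent scale
    ``b``.  Calibrated to plausible European magnitudes (q60 for men roughly
    1%, q80 roughly 6%); it is a stand-in for a national table, not real
    registry data.
    """
    rows = []
    for sex, b in (("m", gompertz_b_male), ("f", gompertz_b_female)):
        ages = np.arange(0, max_age + 1)
        mu = makeham_a + b * gompertz_c**ages
        qx = 1.0 - np.exp(-mu)
        qx[-1] = 1.0
        rows.append(pd.DataFrame({"age": ages, "sex": sex, "qx": qx}))
    return LifeTable(pd.concat(rows, ignore_index=True))


def load_bundled_life_table() -> LifeTable:
    """Load the bundled synthetic Greek-like life table fixture."""
    ref = importlib.resources.files("chfcea") / "data" / "life_table_synthetic_greek.csv"
    with importlib.resources.as_file(ref) as path:
        return read_life_table(path)


def monthly_noncv_survival(
    table: LifeTable,
    age0: float,
    female_fraction: float,
    t_months,
) -> np.ndarray | float:
    """Probability of remaining free of non-CV death through month ``t``.

    The cohort is a mixture of the two sexes (mixture of survival curves,
    not of hazards); within each attained year of age the monthly survival
    factor is ``(1 - qx)**(1/12)``.
    """
    t = np.atleast_1d(np.asarray(t_months, dtype=int))
    if (t < 0).any():
        raise ValueError("t_months must be non-negative")
    n_months = int(t.max()) if t.size else 0
    n_years = n_months // 12 + 1
    curves = {}
    for sex in ("m", "f"):
        q = table.annual_qx_path(age0, n_years, sex)
        monthly = np.repeat((1.0 - q) ** (1.0 / 12.0), 12)[:n_months]
        s = np.concatenate([[1.0], np.cumprod(monthly)])
        curves[sex] = s
    mixed = female_fraction * curves["f"] + (1.0 - female_fraction) * curves["m"]
    out = mixed[t]
    if np.isscalar(t_months) or np.ndim(t_months) == 0:
        return float(out[0])
    return out
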