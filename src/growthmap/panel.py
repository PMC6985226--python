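"""Wide-format longitudinal item panel.

Columns follow the ``item<i>_t<j>`` convention (items 1-based, occasions
1-based); covariates are plain named columns.  Likert responses are treated
as continuous.  Missing item cells encode dropout; covariates must be
complete (rows with missing covariates are dropped with a logged count).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = ["ItemPanel", "item_column"]

log = logging.getLogger(__name__)

_ITEM_RE = re.compile(r"^item(\d+)_t(\d+)$")


def item_column(item: int, occasion: int) -> str:
    """Column name for 1-based item/occasion indices."""
    return f"item{item}_t{occasion}"


@dataclass
class ItemPanel:
    """Item responses across occasions plus baseline covariates.

    ``df`` holds one row per participant; item columns are
    ``item1_t1 ... item<I>_t<T>``, everything else is a covariate.
    """

    df: pd.DataFrame
    n_items: int
    n_occasions: int
    item_labels: List[str] = field(default_factory=list)
    occasion_labels: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.item_labels:
            self.item_labels = [f"item{i}" for i in range(1, self.n_items + 1)]
        if not self.occasion_labels:
            self.occasion_labels = [f"t{j}" for j in range(1, self.n_occasions + 1)]
        missing_cols = [c for c in self.item_columns if c not in self.df.columns]
        if missing_cols:
            raise ValueError(f"panel is missing item columns: {missing_cols[:5]} ...")
        self._validate()

    # -- structure ------------------------------------------------------------

    @property
    def item_columns(self) -> List[str]:
        return [
            item_column(i, j)
            for j in range(1, self.n_occasions + 1)
            for i in range(1, self.n_items + 1)
        ]

    def occasion_columns(self, occasion: int) -> List[str]:
        return [item_column(i, occasion) for i in range(1, self.n_items + 1)]

    @property
    def covariate_columns(self) -> List[str]:
        items = set(self.item_columns)
        return [c for c in self.df.columns if c not in items]

    @property
    def n(self) -> int:
        return len(self.df)

    def _validate(self) -> None:
        # every participant must contribute at least one fully/partly observed occasion
        any_obs = np.zeros(len(self.df), dtype=bool)
        for j in range(1, self.n_occasions + 1):
            any_obs |= self.df[self.occasion_columns(j)].notna().any(axis=1).to_numpy()
        if not any_obs.all():
            bad = int((~any_obs).sum())
            raise ValueError(f"{bad} participants have no observed occasion")
        cov = self.covariate_columns
        if cov:
            keep = self.df[cov].notna().all(axis=1)
            dropped = int((~keep).sum())
            if dropped:
                log.info("dropping %d rows with missing covariates", dropped)
                self.df = self.df.loc[keep].reset_index(drop=True)

    # -- data access ----------------------------------------------------------

    def matrix(self, var_names: Sequence[str]) -> np.ndarray:
        """n x p float matrix for the requested columns (NaN = missing)."""
        missing = [v for v in var_names if v not in self.df.columns]
        if missing:
            raise KeyError(f"panel lacks variables: {missing}")
        return self.df[list(var_names)].to_numpy(dtype=float)

    def occasion_n(self) -> List[int]:
        """Participants with at least one observed item per occasion."""
        return [
            int(self.df[self.occasion_columns(j)].notna().any(axis=1).sum())
            for j in range(1, self.n_occasions + 1)
        ]

    # -- IO -------------------------------------------------------------------

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def from_csv(
        cls,
        path,
        covariates_path=None,
        n_items: Optional[int] = None,
        n_occasions: Optional[int] = None,
    ) -> "ItemPanel":
        df = pd.read_csv(path)
        if covariates_path is not None:
            cov = pd.read_csv(covariates_path)
            if len(cov) != len(df):
                raise ValueError("covariate sidecar row count does not match panel")
            df = pd.concat([df, cov], axis=1)
        found_items, found_occ = 0, 0
        for c in df.columns:
            m = _ITEM_RE.match(c)
            if m:
                found_items = max(found_items, int(m.group(1)))
                found_occ = max(found_occ, int(m.group(2)))
        return cls(
            df=df,
            n_items=n_items or found_items,
            n_occasions=n_occasions or found_occ,
        )
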