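"""Containers and CSV I/O for multi-informant dyad datasets.

A dataset holds, for each parent role (mother / father), the dyads in which
that parent participated: binary conflict-questionnaire item responses from
the adolescent (reporting about that parent) and from the parent, missingness
masks, and the clinician-rated 3-level hopelessness score of the adolescent.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

ROLES = ("mother", "father")
RESPONDENTS = ("adolescent", "parent")


class SchemaError(ValueError):
    """Raised when an input table violates the dataset schema."""


@dataclass
class RoleBlock:
    """All data for the dyads of one parent role.

    Item matrices are ``(n_dyads, n_items)`` int arrays in {0, 1}; entries
    where the observation mask is False are ignored by every likelihood.
    ``outcome`` holds the hopelessness category (1 = absent, 2 = subclinical,
    3 = clinical) per adolescent; ``outcome_mask`` exists so that exact
    leave-one-out refits can hold single outcomes out, the generator never
    produces missing outcomes.
    """

    ids: np.ndarray
    adol_items: np.ndarray
    adol_mask: np.ndarray
    par_items: np.ndarray
    par_mask: np.ndarray
    outcome: np.ndarray
    outcome_mask: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=int)
        self.adol_items = np.asarray(self.adol_items, dtype=int)
        self.par_items = np.asarray(self.par_items, dtype=int)
        self.adol_mask = np.asarray(self.adol_mask, dtype=bool)
        self.par_mask = np.asarray(self.par_mask, dtype=bool)
        self.outcome = np.asarray(self.outcome, dtype=int)
        if self.outcome_mask is None:
            self.outcome_mask = np.ones(self.outcome.shape, dtype=bool)
        self.outcome_mask = np.asarray(self.outcome_mask, dtype=bool)
        n = len(self.ids)
        for arr in (self.adol_items, self.adol_mask, self.par_items, self.par_mask):
            if arr.shape[0] != n:
                raise SchemaError("item matrix row count does not match dyad count")
        if self.outcome.shape != (n,):
            raise SchemaError("outcome length does not match dyad count")
        observed = [self.adol_items[self.adol_mask], self.par_items[self.par_mask]]
        for vals in observed:
            if vals.size and not np.isin(vals, (0, 1)).all():
                raise SchemaError("item responses must be 0/1")
        if n and not np.isin(self.outcome, (1, 2, 3)).all():
            raise SchemaError("hopelessness categories must be in {1, 2, 3}")

    @property
    def n_dyads(self) -> int:
        return len(self.ids)

    @property
    def n_items(self) -> int:
        return self.adol_items.shape[1]

    def drop_outcome(self, index: int) -> "RoleBlock":
        """Return a copy with one outcome observation masked out."""
        mask = self.outcome_mask.copy()
        mask[index] = False
        return replace(self, outcome_mask=mask)


@dataclass
class DyadDataset:
    """Item responses and outcomes for mother- and father-dyads.

    ``n_adolescents`` counts all adolescents in the study; an adolescent
    appears in a role block only if that parent participated.
    """

    n_adolescents: int
    roles: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for role in self.roles:
            if role not in ROLES:
                raise SchemaError(f"unknown parent role {role!r}")
        if not self.roles:
            raise SchemaError("dataset must contain at least one parent role")
        n_items = {blk.n_items for blk in self.roles.values()}
        if len(n_items) > 1:
            raise SchemaError("role blocks must share the item count")

    @property
    def n_items(self) -> int:
        return next(iter(self.roles.values())).n_items

    @property
    def role_names(self):
        return [r for r in ROLES if r in self.roles]

    def participation(self, role: str) -> np.ndarray:
        """Boolean participation indicator over all adolescent ids."""
        out = np.zeros(self.n_adolescents, dtype=bool)
        if role in self.roles:
            out[self.roles[role].ids] = True
        return out


def write_dataset(dataset: DyadDataset, items_csv, outcome_csv) -> None:
    """Write a dataset as two CSVs.

    Long item table: adolescent_id, parent_role, respondent, item, response
    (missing responses as empty cells). Outcome table: adolescent_id,
    parent_role, hopelessness.
    """
    item_rows = []
    outcome_rows = []
    for role in dataset.role_names:
        blk = dataset.roles[role]
        for resp, items, mask in (
            ("adolescent", blk.adol_items, blk.adol_mask),
            ("parent", blk.par_items, blk.par_mask),
        ):
            for i, aid in enumerate(blk.ids):
                for j in range(blk.n_items):
                    item_rows.append(
                        {
                            "adolescent_id": aid,
                            "parent_role": role,
                            "respondent": resp,
                            "item": j,
                            "response": int(items[i, j]) if mask[i, j] else np.nan,
                        }
                    )
        for i, aid in enumerate(blk.ids):
            outcome_rows.append(
                {"adolescent_id": aid, "parent_role": role, "hopelessness": int(blk.outcome[i])}
            )
    pd.DataFrame(item_rows).to_csv(items_csv, index=False)
    pd.DataFrame(outcome_rows).to_csv(outcome_csv, index=False)


def read_dataset(items_csv, outcome_csv) -> DyadDataset:
    """Read a dataset written by :func:`write_dataset`, validating the schema."""
    items = pd.read_csv(items_csv)
    outcomes = pd.read_csv(outcome_csv)
    required = {"adolescent_id", "parent_role", "respondent", "item", "response"}
    if not required.issubset(items.columns):
        raise SchemaError(f"item table missing columns {sorted(required - set(items.columns))}")
    if not {"adolescent_id", "parent_role", "hopelessness"}.issubset(outcomes.columns):
        raise SchemaError("outcome table missing required columns")
    bad = outcomes[~outcomes["hopelessness"].isin([1, 2, 3])]
    if len(bad):
        raise SchemaError(f"hopelessness out of range in rows {bad.index.tolist()}")
    dup = items.duplicated(["adolescent_id", "parent_role", "respondent", "item"])
    if dup.any():
        raise SchemaError(f"duplicate item rows at indices {items.index[dup].tolist()}")
    observed = items["response"].dropna()
    if not observed.isin([0, 1]).all():
        raise SchemaError("item responses must be 0/1 or empty")

    n_items = int(items["item"].max()) + 1
    roles = {}
    for role, sub in items.groupby("parent_role"):
        ids = np.sort(sub["adolescent_id"].unique())
        index = {aid: i for i, aid in enumerate(ids)}
        mats = {}
        masks = {}
        for resp in RESPONDENTS:
            mat = np.zeros((len(ids), n_items), dtype=int)
            mask = np.zeros((len(ids), n_items), dtype=bool)
            rsub = sub[sub["respondent"] == resp]
            rows = rsub["adolescent_id"].map(index).to_numpy()
            cols = rsub["item"].to_numpy()
            vals = rsub["response"].to_numpy()
            ok = ~pd.isna(vals)
            mat[rows[ok], cols[ok]] = vals[ok].astype(int)
            mask[rows[ok], cols[ok]] = True
            mats[resp], masks[resp] = mat, mask
        osub = outcomes[outcomes["parent_role"] == role].set_index("adolescent_id")
        missing = [aid for aid in ids if aid not in osub.index]
        if missing:
            raise SchemaError(f"missing hopelessness for adolescents {missing} ({role})")
        outcome = osub.loc[ids, "hopelessness"].to_numpy()
        roles[role] = RoleBlock(
            ids=ids,
            adol_items=mats["adolescent"],
            adol_mask=masks["adolescent"],
            par_items=mats["parent"],
            par_mask=masks["parent"],
            outcome=outcome,
        )
    n_adol = int(max(items["adolescent_id"].max(), outcomes["adolescent_id"].max())) + 1
    return DyadDataset(n_adolescents=n_adol, roles=roles)
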