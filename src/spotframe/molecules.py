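"""Ragged molecule-level storage for in-situ platforms.

Molecule-based technologies (seqFISH and relatives) detect individual mRNA
molecules with sub-cellular coordinates.  Per (gene, cell) the number of
detected molecules varies, so the natural container is a matrix-shaped
collection of variable-length groups — :class:`MoleculeStore` — alongside
the ordinary integer counts assay that summarizes it.

Records are rows of ``(feature_id, sample_id, barcode_id, x, y[, z])`` in
full-resolution pixel units, the same frame as the spot/cell coordinates.
Extra columns ride along untouched (never interpreted).  Molecules that were
not assigned to any cell are outside the contract: loaders must filter them
out before :func:`build_store` and report the filtered count themselves.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import (
    MalformedRecord,
    NoMoleculeStore,
    UnknownFeature,
    UnknownID,
    UnknownObservation,
)

REQUIRED_COLUMNS = ("feature_id", "sample_id", "barcode_id", "x", "y")


class MoleculeStore:
    """Groups of molecule records keyed by (feature_id, (sample_id, barcode_id)).

    The full (feature x observation) universe comes from the owning dataset:
    pairs without records are empty groups, not missing ones.  Group lookup
    is a dict, so constant time in the number of groups.
    """

    def __init__(self, table: pd.DataFrame, feature_ids, obs_keys):
        self.table = table.reset_index(drop=True)
        self.feature_ids = list(feature_ids)
        self.obs_keys = list(obs_keys)
        self._feature_set = set(self.feature_ids)
        self._obs_set = set(self.obs_keys)
        self._groups = {}
        if len(self.table):
            grouped = self.table.groupby(
                ["feature_id", "sample_id", "barcode_id"], sort=False
            ).indices
            for (f, s, b), idx in grouped.items():
                self._groups[(f, (s, b))] = np.asarray(idx)

    @property
    def total_molecules(self) -> int:
        return len(self.table)

    def group_size(self, feature_id, obs_key) -> int:
        self._check(feature_id, obs_key)
        idx = self._groups.get((feature_id, tuple(obs_key)))
        return 0 if idx is None else len(idx)

    def group(self, feature_id, obs_key) -> pd.DataFrame:
        """Records of one (feature, observation) group; empty frame if none."""
        self._check(feature_id, obs_key)
        idx = self._groups.get((feature_id, tuple(obs_key)))
        if idx is None:
            return self.table.iloc[0:0]
        return self.table.iloc[idx]

    def _check(self, feature_id, obs_key):
        if feature_id not in self._feature_set:
            raise UnknownID(f"unknown feature {feature_id!r}")
        if tuple(obs_key) not in self._obs_set:
            raise UnknownID(f"unknown observation {tuple(obs_key)!r}")

    def restricted(self, feature_ids, obs_keys) -> "MoleculeStore":
        """Store over a reduced universe; drops exactly the lost groups."""
        fset, oset = set(feature_ids), set(map(tuple, obs_keys))
        if len(self.table):
            keep = (
                self.table["feature_id"].isin(fset).to_numpy()
                & pd.Series(
                    list(zip(self.table["sample_id"], self.table["barcode_id"]))
                ).isin(oset).to_numpy()
            )
            table = self.table.loc[keep]
        else:
            table = self.table
        return MoleculeStore(table, feature_ids, obs_keys)

    def renamed_samples(self, mapping) -> "MoleculeStore":
        table = self.table.copy()
        if len(table):
            table["sample_id"] = table["sample_id"].map(lambda s: mapping.get(s, s))
        obs_keys = [(mapping.get(s, s), b) for s, b in self.obs_keys]
        return MoleculeStore(table, self.feature_ids, obs_keys)

    @staticmethod
    def concat(stores) -> "MoleculeStore":
        stores = list(stores)
        table = pd.concat([s.table for s in stores], ignore_index=True)
        obs_keys = [k for s in stores for k in s.obs_keys]
        return MoleculeStore(table, stores[0].feature_ids, obs_keys)

    def __repr__(self):
        return (
            f"<MoleculeStore {self.total_molecules} molecules over "
            f"{len(self.feature_ids)} features x {len(self.obs_keys)} observations>"
        )


def build_store(record_table: pd.DataFrame, dataset) -> MoleculeStore:
    """Validate a record table against a dataset and attach the store.

    The dataset supplies the legal feature/observation universe; unknown
    features or observations and non-finite coordinates are errors, not
    silently dropped rows.  The store is attached to the dataset under the
    assay-slot name ``"molecules"`` (``dataset.assay("molecules")``).
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in record_table.columns]
    if missing:
        raise MalformedRecord(f"record table lacks column(s) {missing}")
    table = record_table.reset_index(drop=True).copy()
    coord_cols = ["x", "y"] + (["z"] if "z" in table.columns else [])
    for c in coord_cols:
        table[c] = pd.to_numeric(table[c])
        if c in ("x", "y") and not np.isfinite(table[c].to_numpy(dtype=float)).all():
            n_bad = int((~np.isfinite(table[c].to_numpy(dtype=float))).sum())
            raise MalformedRecord(f"{n_bad} record(s) with non-finite {c}")

    feature_ids = dataset.feature_ids
    obs_keys = dataset.obs_keys
    bad_f = sorted(set(table["feature_id"]) - set(feature_ids))
    if bad_f:
        raise UnknownFeature(f"record feature(s) not in dataset: {bad_f[:5]}")
    keys = set(zip(table["sample_id"], table["barcode_id"]))
    bad_o = sorted(keys - set(obs_keys))
    if bad_o:
        raise UnknownObservation(f"record observation(s) not in dataset: {bad_o[:5]}")

    store = MoleculeStore(table, feature_ids, obs_keys)
    dataset.molecules = store
    return store


def counts_from_molecules(store: MoleculeStore) -> np.ndarray:
    """Feature-by-observation integer matrix of group sizes.

    Entry (f, o) is the number of molecules in group (f, o); dimensions match
    the owning dataset's universe, including all-empty rows/columns.
    """
    n_f, n_o = len(store.feature_ids), len(store.obs_keys)
    counts = np.zeros((n_f, n_o), dtype=np.int64)
    f_pos = {f: i for i, f in enumerate(store.feature_ids)}
    o_pos = {k: j for j, k in enumerate(store.obs_keys)}
    for (f, key), idx in store._groups.items():
        counts[f_pos[f], o_pos[key]] = len(idx)
    return counts


def molecules_of(store: MoleculeStore, features=None, obs=None) -> pd.DataFrame:
    """Flat table of records matching the selectors, coordinates bit-exact.

    Selectors follow dataset subsetting: ``None`` (all), integer lists,
    boolean masks, or ID lists (feature_id / (sample_id, barcode_id) pairs
    or bare barcode_ids).
    """
    fids = _pick(features, store.feature_ids, "feature")
    okeys = _pick_obs(obs, store.obs_keys)
    if store.total_molecules == 0:
        return store.table
    fset, oset = set(fids), set(map(tuple, okeys))
    keep = (
        store.table["feature_id"].isin(fset).to_numpy()
        & pd.Series(
            list(zip(store.table["sample_id"], store.table["barcode_id"]))
        ).isin(oset).to_numpy()
    )
    return store.table.loc[keep]


def _pick(selector, universe, axis):
    if selector is None:
        return list(universe)
    arr = np.asarray(selector)
    if arr.dtype == bool:
        if arr.shape != (len(universe),):
            raise UnknownID(f"boolean {axis} mask length {arr.shape} != {len(universe)}")
        return [u for u, k in zip(universe, arr) if k]
    if arr.dtype.kind in "iu":
        return [universe[int(i)] for i in arr]
    out = []
    known = set(universe)
    for val in selector:
        if val not in known:
            raise UnknownID(f"unknown {axis} ID {val!r}")
        out.append(val)
    return out


def _pick_obs(selector, obs_keys):
    if selector is None:
        return list(obs_keys)
    sel = list(selector)
    if sel and isinstance(sel[0], tuple):
        known = set(obs_keys)
        for k in sel:
            if tuple(k) not in known:
                raise UnknownID(f"unknown observation {k!r}")
        return [tuple(k) for k in sel]
    arr = np.asarray(selector)
    if arr.dtype == bool or arr.dtype.kind in "iu":
        return _pick(selector, obs_keys, "observation")
    # bare barcode ids
    by_barcode = {}
    for key in obs_keys:
        by_barcode.setdefault(key[1], []).append(key)
    out = []
    for b in sel:
        hits = by_barcode.get(b)
        if not hits:
            raise UnknownID(f"unknown observation barcode {b!r}")
        out.extend(hits)
    return out


def require_store(dataset) -> MoleculeStore:
    if dataset.molecules is None:
        raise NoMoleculeStore("dataset has no attached molecule store")
    return dataset.molecules


def read_molecule_csv(path) -> pd.DataFrame:
    """Read a molecule record table (CSV with header)."""
    return pd.read_csv(path)


def write_molecule_csv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)
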