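"""Feature-table I/O, taxonomy collapse and relative abundance.

A feature table is a samples x taxa count matrix stored taxa-as-rows in a
classic tab-separated layout: first column the taxon id, second column a
7-rank Greengenes-style lineage string (``k__...; p__...; ...; s__...``),
then one integer column per sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RANKS",
    "RANK_PREFIXES",
    "FeatureTable",
    "AbundanceMatrix",
    "read_feature_table",
    "write_feature_table",
    "collapse_taxonomy",
    "collapse_best_rank",
    "relative_abundance",
    "parse_lineage",
]

logger = logging.getLogger(__name__)

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")
RANK_PREFIXES = ("k__", "p__", "c__", "o__", "f__", "g__", "s__")

_ID_COL = "taxon_id"
_LINEAGE_COL = "lineage"


def parse_lineage(lineage: str) -> list[str]:
    """Split a lineage string into its 7 rank labels (prefixes retained).

    Accepts ``;`` separators with optional following space; missing trailing
    ranks are padded with bare prefixes. Malformed fields are kept verbatim
    with a warning.
    """
    parts = [p.strip() for p in str(lineage).split(";")]
    out = []
    for i, prefix in enumerate(RANK_PREFIXES):
        if i < len(parts) and parts[i]:
            field_ = parts[i]
            if not field_.startswith(prefix):
                logger.warning("lineage field %r lacks expected prefix %r; kept verbatim", field_, prefix)
            out.append(field_)
        else:
            out.append(prefix)
    return out


def rank_label(lineage: str, rank: str) -> str:
    """The label at ``rank`` ('' when unnamed, prefix stripped)."""
    idx = RANKS.index(rank)
    token = parse_lineage(lineage)[idx]
    prefix = RANK_PREFIXES[idx]
    return token[len(prefix):] if token.startswith(prefix) else token


@dataclass
class FeatureTable:
    """Counts of taxa (rows) across samples (columns) with lineages."""

    counts: np.ndarray
    taxon_ids: list[str]
    sample_ids: list[str]
    lineages: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D (taxa x samples) array")
        self.taxon_ids = [str(t) for t in self.taxon_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.lineages = [str(l) for l in self.lineages]
        nt, ns = self.counts.shape
        if len(self.taxon_ids) != nt or len(self.lineages) != nt:
            raise ValueError("taxon_ids/lineages length must match the count-matrix rows")
        if len(self.sample_ids) != ns:
            raise ValueError("sample_ids length must match the count-matrix columns")
        if len(set(self.taxon_ids)) != nt:
            raise ValueError("duplicate taxon ids")
        if len(set(self.sample_ids)) != ns:
            raise ValueError("duplicate sample ids")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.allclose(self.counts, np.round(self.counts)):
                raise ValueError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).any():
            t, s = np.argwhere(self.counts < 0)[0]
            raise ValueError(
                f"negative count at taxon {self.taxon_ids[t]!r}, sample {self.sample_ids[s]!r}"
            )

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def sample_sums(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, columns=self.sample_ids)
        df.insert(0, _LINEAGE_COL, self.lineages)
        df.insert(0, _ID_COL, self.taxon_ids)
        return df


@dataclass
class AbundanceMatrix:
    """Per-sample proportions (taxa x samples); columns sum to 1 or are all-zero."""

    values: np.ndarray
    taxon_ids: list[str]
    sample_ids: list[str]
    rank: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        sums = self.values.sum(axis=0)
        ok = np.isclose(sums, 1.0, atol=1e-9) | (sums == 0.0)
        if not ok.all():
            bad = np.asarray(self.sample_ids)[~ok]
            raise ValueError(f"abundance columns must sum to 1 (or 0): {list(bad)}")
        if self.rank is not None and self.rank not in RANKS:
            raise ValueError(f"unknown rank {self.rank!r}")


def read_feature_table(path) -> FeatureTable:
    """Parse a taxa-rows TSV; errors name the offending cell or id."""
    df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
    if df.shape[1] < 3:
        raise ValueError("feature table needs taxon id, lineage and >= 1 sample column")
    id_col, lineage_col = df.columns[0], df.columns[1]
    sample_ids = [str(c) for c in df.columns[2:]]
    taxon_ids = df[id_col].astype(str).tolist()
    lineages = df[lineage_col].astype(str).tolist()
    raw = df[df.columns[2:]].to_numpy()
    counts = np.zeros(raw.shape, dtype=np.int64)
    for t in range(raw.shape[0]):
        for s in range(raw.shape[1]):
            v = raw[t, s]
            fv = float(v)
            if not float(fv).is_integer() or fv < 0:
                raise ValueError(
                    f"count must be a nonnegative integer at taxon {taxon_ids[t]!r}, "
                    f"sample {sample_ids[s]!r}: got {v!r}"
                )
            counts[t, s] = int(fv)
    return FeatureTable(counts=counts, taxon_ids=taxon_ids, sample_ids=sample_ids, lineages=lineages)


def write_feature_table(table: FeatureTable, path) -> None:
    table.to_dataframe().to_csv(path, sep="\t", index=False)


def _collapse_by_keys(table: FeatureTable, keys, ids, lineages) -> FeatureTable:
    order: dict[str, int] = {}
    for k in keys:
        order.setdefault(k, len(order))
    nt = len(order)
    counts = np.zeros((nt, table.n_samples), dtype=np.int64)
    new_ids = [""] * nt
    new_lineages = [""] * nt
    for row, key in enumerate(keys):
        g = order[key]
        counts[g] += table.counts[row]
        if not new_ids[g]:
            new_ids[g] = ids[row]
            new_lineages[g] = lineages[row]
    # disambiguate colliding display ids (same rank label, different upstream lineage)
    seen: dict[str, int] = {}
    for i, tid in enumerate(new_ids):
        if tid in seen:
            seen[tid] += 1
            new_ids[i] = f"{tid}__{seen[tid]}"
        else:
            seen[tid] = 0
    return FeatureTable(counts=counts, taxon_ids=new_ids, sample_ids=list(table.sample_ids), lineages=new_lineages)


def collapse_taxonomy(table: FeatureTable, rank: str) -> FeatureTable:
    """Sum rows sharing the lineage prefix through ``rank``.

    Taxa with an empty label at ``rank`` are pooled into a single
    ``unclassified at <rank>`` row. Per-sample totals are conserved.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
    idx = RANKS.index(rank)
    keys, ids, lineages = [], [], []
    for lineage in table.lineages:
        parts = parse_lineage(lineage)
        label = parts[idx][len(RANK_PREFIXES[idx]):]
        if label:
            prefix = parts[: idx + 1]
            keys.append(";".join(prefix))
            ids.append(parts[idx])
            lineages.append(";".join(prefix + list(RANK_PREFIXES[idx + 1 :])))
        else:
            keys.append(f"__unclassified_at_{rank}__")
            ids.append(f"unclassified at {rank}")
            lineages.append(";".join(RANK_PREFIXES))
    return _collapse_by_keys(table, keys, ids, lineages)


def collapse_best_rank(table: FeatureTable) -> FeatureTable:
    """Collapse each taxon at its finest named rank (mixed-rank feature mode)."""
    keys, ids, lineages = [], [], []
    for lineage in table.lineages:
        parts = parse_lineage(lineage)
        best = -1
        for i in range(len(RANKS) - 1, -1, -1):
            if parts[i][len(RANK_PREFIXES[i]):]:
                best = i
                break
        if best < 0:
            keys.append("__unclassified__")
            ids.append("unclassified")
            lineages.append(";".join(RANK_PREFIXES))
        else:
            prefix = parts[: best + 1]
            keys.append(";".join(prefix))
            ids.append(parts[best])
            lineages.append(";".join(prefix + list(RANK_PREFIXES[best + 1 :])))
    return _collapse_by_keys(table, keys, ids, lineages)


def relative_abundance(table: FeatureTable, rank: str | None = None) -> AbundanceMatrix:
    """Column-normalise counts to proportions; all-zero samples stay zero."""
    sums = table.sample_sums().astype(float)
    empty = sums == 0
    if empty.any():
        logger.warning(
            "all-zero samples left as zero columns: %s",
            [s for s, e in zip(table.sample_ids, empty) if e],
        )
    safe = np.where(empty, 1.0, sums)
    values = table.counts / safe
    return AbundanceMatrix(
        values=values,
        taxon_ids=list(table.taxon_ids),
        sample_ids=list(table.sample_ids),
        rank=rank,
    )
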