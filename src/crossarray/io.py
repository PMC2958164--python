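"""Tabular I/O for probe-level expression data and the presence-on-all-chips filter.

Cross-species hybridization leaves many probes indistinguishable from
background, so each intensity comes with a per-chip presence/absence call.
Downstream analysis is restricted to probesets called present on *every*
chip: when the signal is weak there is no way to tell an inactive gene from
a probe that simply does not match the foreign transcript, so only probes
with a quantifiable signal everywhere are kept.

File dialects
-------------
* Expression matrix: TSV, first column ``probe_id``, header row of sample ids,
  nonnegative decimal intensities on the linear scale.
* Calls matrix: TSV of identical shape with values ``P``/``A``/``M``
  (Affymetrix letters) or ``1``/``0``. ``M`` (marginal) is treated as absent:
  weak cross-species signal is uninterpretable.
* Groups: two-column TSV mapping sample id to group label (header optional).
* Annotation: CSV with header ``probe_id,gene_symbol``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import EmptyResultError, FormatError

logger = logging.getLogger(__name__)

_CALL_TO_BOOL = {"P": True, "A": False, "M": False, "1": True, "0": False}


@dataclass
class ExpressionMatrix:
    """Probe x sample intensity table with presence flags and group labels.

    Attributes
    ----------
    intensities : DataFrame
        Nonnegative fluorescence intensities, probes as rows, samples as columns.
    present : DataFrame
        Boolean presence calls, same shape and labels as ``intensities``.
    groups : Series
        Maps each sample id to its group label (e.g. pup/juvenile/adult).
    """

    intensities: pd.DataFrame
    present: pd.DataFrame
    groups: pd.Series = field(repr=False)

    def __post_init__(self) -> None:
        ints, pres = self.intensities, self.present
        if ints.shape != pres.shape:
            raise FormatError(
                f"intensities {ints.shape} and presence {pres.shape} shapes differ"
            )
        if list(ints.index) != list(pres.index) or list(ints.columns) != list(pres.columns):
            raise FormatError("intensities and presence labels differ")
        if ints.index.has_duplicates:
            dups = ints.index[ints.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate probe ids: {dups[:5]}")
        if ints.columns.has_duplicates:
            raise FormatError("duplicate sample ids")
        vals = ints.to_numpy()
        if not np.issubdtype(vals.dtype, np.number):
            raise FormatError("non-numeric intensity values")
        if np.isnan(vals).any():
            raise FormatError("missing intensity values")
        if (vals < 0).any():
            raise FormatError("negative intensity values")
        missing = [s for s in ints.columns if s not in self.groups.index]
        if missing:
            raise FormatError(f"samples missing from groups file: {missing}")
        # keep only relevant samples, in matrix order
        self.groups = self.groups.loc[ints.columns].astype(str)
        self.present = pres.astype(bool)

    # -- convenience accessors -------------------------------------------------

    @property
    def probe_ids(self) -> list[str]:
        return list(self.intensities.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.intensities.columns)

    @property
    def n_probes(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[1]

    @property
    def group_labels(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.groups:
            seen.setdefault(g, None)
        return list(seen)

    def samples_in_group(self, label: str) -> list[str]:
        return [s for s in self.sample_ids if self.groups[s] == label]

    def subset_probes(self, probe_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(
            intensities=self.intensities.loc[probe_ids].copy(),
            present=self.present.loc[probe_ids].copy(),
            groups=self.groups.copy(),
        )

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(
            intensities=self.intensities[list(sample_ids)].copy(),
            present=self.present[list(sample_ids)].copy(),
            groups=self.groups.copy(),
        )


@dataclass(frozen=True)
class ProbeGeneMap:
    """Probe id -> gene symbol map (many probes may target one gene)."""

    entries: dict[str, str]

    def __post_init__(self) -> None:
        for probe, gene in self.entries.items():
            if not isinstance(gene, str) or not gene:
                raise FormatError(f"empty gene symbol for probe {probe!r}")

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, probe: str) -> bool:
        return probe in self.entries

    @property
    def genes(self) -> set[str]:
        return set(self.entries.values())


def _read_groups(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    if df.shape[1] != 2:
        raise FormatError(f"groups file must have 2 columns, got {df.shape[1]}")
    if list(df.iloc[0]) == ["sample_id", "group"]:
        df = df.iloc[1:]
    if df.iloc[:, 0].duplicated().any():
        raise FormatError("duplicate sample id in groups file")
    return pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].values, name="group")


def read_expression_matrix(matrix_path, groups_path, calls_path=None) -> ExpressionMatrix:
    """Read intensity TSV (+ optional calls TSV) and a sample->group map.

    Without a calls file presence is derived as ``intensity > 0``, which lets
    purely synthetic matrices omit the calls file.
    """
    # round_trip parsing so written matrices read back bit-identically
    ints = pd.read_csv(matrix_path, sep="\t", index_col=0, float_precision="round_trip")
    groups = _read_groups(groups_path)
    if calls_path is not None:
        calls = pd.read_csv(calls_path, sep="\t", index_col=0, dtype=str)
        if calls.shape != ints.shape:
            raise FormatError(
                f"calls shape {calls.shape} does not match matrix shape {ints.shape}"
            )
        if list(calls.index) != list(ints.index) or list(calls.columns) != list(ints.columns):
            raise FormatError("calls labels do not match matrix labels")
        flat = calls.to_numpy().ravel()
        bad = sorted(set(flat) - set(_CALL_TO_BOOL))
        if bad:
            raise FormatError(f"unrecognized presence calls: {bad[:5]}")
        present = calls.map(lambda c: _CALL_TO_BOOL[c])
    else:
        present = ints > 0
    return ExpressionMatrix(intensities=ints, present=present, groups=groups)


def write_expression_matrix(
    m: ExpressionMatrix, matrix_path, calls_path=None, groups_path=None
) -> None:
    """Write the matrix (and optionally calls/groups) in the TSV dialects above.

    Floats are written with shortest round-trip repr, so read-back reproduces
    intensities bit-identically.
    """
    Path(matrix_path).parent.mkdir(parents=True, exist_ok=True)
    m.intensities.rename_axis("probe_id").to_csv(matrix_path, sep="\t")
    if calls_path is not None:
        calls = m.present.map(lambda b: "P" if b else "A")
        calls.rename_axis("probe_id").to_csv(calls_path, sep="\t")
    if groups_path is not None:
        m.groups.rename_axis("sample_id").to_csv(groups_path, sep="\t", header=False)


def filter_present_on_all(m: ExpressionMatrix) -> ExpressionMatrix:
    """Keep only probes called present on every chip.

    Row and sample order are preserved. Raises :class:`EmptyResultError` when
    no probe survives — the hallmark of an unusable hybridization.
    """
    mask = m.present.all(axis=1)
    if not mask.any():
        raise EmptyResultError("no probe is present on all samples")
    kept = m.subset_probes(m.intensities.index[mask])
    logger.info("presence filter: %d of %d probes retained", kept.n_probes, m.n_probes)
    return kept


def read_annotation(path) -> ProbeGeneMap:
    """Read a probe_id,gene_symbol CSV into a :class:`ProbeGeneMap`.

    Rows with an empty gene symbol are skipped (counted in the log); identical
    duplicate rows collapse silently, conflicting ones are an error.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"probe_id", "gene_symbol"}
    if not required.issubset(df.columns):
        raise FormatError(f"annotation must have columns {sorted(required)}")
    entries: dict[str, str] = {}
    skipped = 0
    for probe, gene in zip(df["probe_id"], df["gene_symbol"]):
        if gene == "":
            skipped += 1
            continue
        if probe in entries and entries[probe] != gene:
            raise FormatError(
                f"probe {probe!r} maps to both {entries[probe]!r} and {gene!r}"
            )
        entries[probe] = gene
    if skipped:
        logger.info("annotation: skipped %d rows with empty gene symbol", skipped)
    return ProbeGeneMap(entries=entries)
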