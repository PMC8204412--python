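"""Splice-event tables, expression and clinical tables: parsing, validation, filtering.

PSI (percent spliced in) is stored as a fraction in [0, 1]; missing values are
``NaN``. Event identifiers follow the ``GENE_TYPE_ASID`` dialect used by
SpliceSeq-style tables (e.g. ``SLC2A11_ES_61347``); gene symbols containing
underscores are rejected because they make the dialect ambiguous.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: The seven splice modes of SpliceSeq event tables: alternate acceptor,
#: alternate donor, alternate promoter, alternate terminator, exon skip,
#: mutually exclusive exons, retained intron.
SPLICE_TYPES = ("AA", "AD", "AP", "AT", "ES", "ME", "RI")

_ANNOT_COLS = ("symbol", "as_id", "splice_type")

#: Tokens treated as a missing PSI value when reading tables.
NA_TOKENS = {"", "na", "nan", "null", "none", "."}


class ParseError(ValueError):
    """Raised when an input table violates the expected dialect."""


@dataclass(frozen=True)
class SpliceEvent:
    """A single alternative-splicing event.

    The event id round-trips to its components:
    ``SpliceEvent.from_event_id(ev.event_id) == ev``.
    """

    gene_symbol: str
    splice_type: str
    as_id: int

    def __post_init__(self) -> None:
        if self.splice_type not in SPLICE_TYPES:
            raise ParseError(
                f"unknown splice type {self.splice_type!r}; expected one of {SPLICE_TYPES}"
            )
        if "_" in self.gene_symbol or not self.gene_symbol:
            raise ParseError(
                f"gene symbol {self.gene_symbol!r} must be non-empty and underscore-free"
            )

    @property
    def event_id(self) -> str:
        return f"{self.gene_symbol}_{self.splice_type}_{self.as_id}"

    @classmethod
    def from_event_id(cls, event_id: str) -> "SpliceEvent":
        parts = event_id.split("_")
        if len(parts) != 3:
            raise ParseError(f"event id {event_id!r} is not GENE_TYPE_ASID")
        gene, stype, as_id = parts
        try:
            as_num = int(as_id)
        except ValueError as exc:
            raise ParseError(f"event id {event_id!r}: as_id {as_id!r} not an integer") from exc
        return cls(gene, stype, as_num)


class PsiMatrix:
    """Events x samples PSI values with explicit missingness.

    Parameters
    ----------
    psi
        DataFrame indexed by event id, one column per sample, values in
        [0, 1] or NaN.
    events
        Optional list of :class:`SpliceEvent` parallel to the rows; derived
        from the index when omitted.
    """

    def __init__(self, psi: pd.DataFrame, events: list[SpliceEvent] | None = None):
        if psi.index.has_duplicates:
            dup = psi.index[psi.index.duplicated()][0]
            raise ParseError(f"duplicate event id {dup!r}")
        if psi.columns.has_duplicates:
            dup = psi.columns[psi.columns.duplicated()][0]
            raise ParseError(f"duplicate sample id {dup!r}")
        vals = psi.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            if np.nanmin(vals, initial=0.0) < 0 or np.nanmax(vals, initial=1.0) > 1:
                raise ParseError("PSI values must lie in [0, 1] or be missing")
        if events is None:
            events = [SpliceEvent.from_event_id(e) for e in psi.index]
        if len(events) != len(psi):
            raise ValueError("events and psi rows differ in length")
        self.psi = psi.astype(float)
        self.events = events

    @property
    def event_ids(self) -> pd.Index:
        return self.psi.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.psi.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.psi.shape

    def subset_events(self, event_ids: Iterable[str]) -> "PsiMatrix":
        idx = pd.Index(event_ids)
        pos = self.psi.index.get_indexer(idx)
        if (pos < 0).any():
            missing = idx[pos < 0][0]
            raise KeyError(f"event id {missing!r} not in matrix")
        return PsiMatrix(self.psi.loc[idx], [self.events[i] for i in pos])

    def subset_samples(self, sample_ids: Iterable[str]) -> "PsiMatrix":
        return PsiMatrix(self.psi.loc[:, list(sample_ids)], list(self.events))

    def annotations(self) -> pd.DataFrame:
        """Per-event annotation table (symbol, as_id, splice_type)."""
        return pd.DataFrame(
            {
                "symbol": [e.gene_symbol for e in self.events],
                "as_id": [e.as_id for e in self.events],
                "splice_type": [e.splice_type for e in self.events],
            },
            index=self.event_ids,
        )


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values.

    ``values`` are non-negative on the linear scale; ``is_log`` declares that
    the matrix is already log2-transformed (then negativity is allowed).
    """

    values: pd.DataFrame
    is_log: bool = False

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates or self.values.columns.has_duplicates:
            raise ParseError("duplicate gene or sample ids in expression matrix")
        if not self.is_log and (self.values.to_numpy() < 0).any():
            raise ParseError("negative values in a linear-scale expression matrix")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def log2p(self) -> pd.DataFrame:
        """log2(x + 1) view (identity when already log-scale)."""
        return self.values if self.is_log else np.log2(self.values + 1.0)


@dataclass
class FilterReport:
    n_input: int
    n_kept: int
    n_dropped_missing: int
    n_dropped_low_mean: int
    min_observed_frac: float
    min_mean_psi: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.__dict__])


def compute_psi(inclusion, exclusion):
    """PSI = inclusion / (inclusion + exclusion); NaN when both counts are 0.

    Accepts scalars or arrays of non-negative read counts. A count of zero on
    both sides carries no evidence for either splice form, so the value is
    missing rather than zero.
    """
    inc = np.asarray(inclusion, dtype=float)
    exc = np.asarray(exclusion, dtype=float)
    if (inc < 0).any() or (exc < 0).any():
        raise ValueError("read counts must be non-negative")
    total = inc + exc
    with np.errstate(invalid="ignore", divide="ignore"):
        psi = np.where(total > 0, inc / np.where(total > 0, total, 1.0), np.nan)
    if np.isscalar(inclusion) and np.isscalar(exclusion):
        return float(psi) if not np.isnan(psi) else float("nan")
    return psi


def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype=str)


def read_psi_table(path) -> PsiMatrix:
    """Read a SpliceSeq-style PSI table.

    Expected columns: ``symbol``, ``as_id``, ``splice_type``, then one column
    per sample. Values on a percent scale (table maximum > 1.5) are rescaled
    to fractions with a logged warning; a table whose maximum exceeds 1.5 but
    whose values are mostly <= 1 is rejected as mixed-scale.
    """
    df = _read_tsv(path)
    if df.empty:
        raise ParseError(f"{path}: no events")
    missing_cols = [c for c in _ANNOT_COLS if c not in df.columns]
    if missing_cols:
        raise ParseError(f"{path}: missing annotation columns {missing_cols}")
    sample_cols = [c for c in df.columns if c not in _ANNOT_COLS]
    if not sample_cols:
        raise ParseError(f"{path}: no sample columns")

    events: list[SpliceEvent] = []
    for lineno, row in enumerate(df.itertuples(index=False), start=2):
        try:
            events.append(
                SpliceEvent(str(row.symbol), str(row.splice_type), int(row.as_id))
            )
        except (ParseError, ValueError) as exc:
            raise ParseError(f"{path}: line {lineno}: {exc}") from exc

    raw = df[sample_cols].map(
        lambda s: np.nan if str(s).strip().lower() in NA_TOKENS else float(s)
    )
    vals = raw.to_numpy(dtype=float)
    finite = vals[np.isfinite(vals)]
    if finite.size and np.nanmax(finite) > 1.5:
        # whole-table percent dialect; a mostly-fractional table with a stray
        # large cell is ambiguous and rejected.
        frac_like = (finite <= 1.0).mean()
        if frac_like > 0.5:
            raise ParseError(
                f"{path}: mixed value scales (max {np.nanmax(finite):g} looks like a "
                f"percentage but {frac_like:.0%} of values are <= 1)"
            )
        if np.nanmax(finite) > 100.0:
            raise ParseError(f"{path}: PSI value {np.nanmax(finite):g} exceeds 100")
        logger.warning("%s: values on percent scale; rescaling to fractions", path)
        vals = vals / 100.0
    psi = pd.DataFrame(vals, index=[e.event_id for e in events], columns=sample_cols)
    return PsiMatrix(psi, events)


def write_psi_table(m: PsiMatrix, path, seed: int | None = None) -> None:
    df = pd.concat([m.annotations(), m.psi], axis=1)
    _write_tsv(df, path, seed=seed, index=False)


def _write_tsv(df: pd.DataFrame, path, seed: int | None = None, index: bool = True) -> None:
    with open(path, "w") as fh:
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        df.to_csv(fh, sep="\t", index=index, float_format="%.6f")


def read_expression_table(path, is_log: bool = False) -> ExpressionMatrix:
    df = _read_tsv(path)
    gene_col = df.columns[0]
    mat = df.set_index(gene_col).astype(float)
    mat.index.name = "gene_id"
    return ExpressionMatrix(mat, is_log=is_log)


def write_expression_table(e: ExpressionMatrix, path, seed: int | None = None) -> None:
    _write_tsv(e.values, path, seed=seed)


CLINICAL_COLUMNS = (
    "sample_id",
    "tissue_type",
    "stage",
    "T",
    "N",
    "M",
    "gender",
    "smoking_history",
    "os_time",
    "os_event",
)


def read_clinical_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    if "sample_id" not in df.columns:
        raise ParseError(f"{path}: clinical table lacks 'sample_id'")
    df = df.set_index("sample_id")
    if "os_time" in df.columns:
        df["os_time"] = df["os_time"].astype(float)
        if (df["os_time"].dropna() <= 0).any():
            raise ParseError(f"{path}: os_time must be > 0")
    if "os_event" in df.columns:
        ev = df["os_event"].dropna()
        if not ev.isin([0, 1]).all():
            raise ParseError(f"{path}: os_event must be 0/1")
    return df


def write_clinical_table(df: pd.DataFrame, path, seed: int | None = None) -> None:
    _write_tsv(df, path, seed=seed)


def filter_events(
    m: PsiMatrix,
    min_observed_frac: float = 0.8,
    min_mean_psi: float = 0.05,
) -> tuple[PsiMatrix, FilterReport]:
    """Apply the standard event-quality filters.

    An event is kept when at least ``min_observed_frac`` of samples have a PSI
    value AND its mean PSI over the observed samples is at least
    ``min_mean_psi``. The operation is idempotent and preserves event order.
    """
    vals = m.psi.to_numpy(dtype=float)
    n_samples = vals.shape[1]
    observed = np.isfinite(vals)
    obs_frac = observed.sum(axis=1) / max(n_samples, 1)
    counts = observed.sum(axis=1)
    sums = np.where(observed, vals, 0.0).sum(axis=1)
    means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    cov_ok = obs_frac >= min_observed_frac
    mean_ok = np.isfinite(means) & (means >= min_mean_psi)
    keep = cov_ok & mean_ok
    report = FilterReport(
        n_input=len(m.events),
        n_kept=int(keep.sum()),
        n_dropped_missing=int((~cov_ok).sum()),
        n_dropped_low_mean=int((cov_ok & ~mean_ok).sum()),
        min_observed_frac=min_observed_frac,
        min_mean_psi=min_mean_psi,
    )
    kept = PsiMatrix(m.psi.loc[keep], [e for e, k in zip(m.events, keep) if k])
    return kept, report


def splice_mode_membership(
    m: PsiMatrix,
) -> tuple[Mapping[str, frozenset[str]], pd.DataFrame]:
    """Per-gene set of splice modes and the gene count per mode combination.

    The combination table is the input for an UpSet-style plot: one row per
    observed subset of the seven splice modes, with the number of genes whose
    mode set equals that subset exactly.
    """
    membership: dict[str, set[str]] = {}
    for e in m.events:
        membership.setdefault(e.gene_symbol, set()).add(e.splice_type)
    frozen = {g: frozenset(s) for g, s in membership.items()}
    combos: dict[frozenset[str], int] = {}
    for s in frozen.values():
        combos[s] = combos.get(s, 0) + 1
    rows = [
        {"combination": "+".join(sorted(c, key=SPLICE_TYPES.index)), "n_types": len(c), "n_genes": n}
        for c, n in combos.items()
    ]
    table = pd.DataFrame(rows, columns=["combination", "n_types", "n_genes"])
    table = table.sort_values(["n_genes", "combination"], ascending=[False, True]).reset_index(drop=True)
    return frozen, table
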