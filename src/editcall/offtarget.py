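"""Per-site nuclease-minus-mock indel differentials and their aggregation.

An off-target screen compares, at the intended target site and a panel of
predicted off-target sites, the indel percentage in a nuclease-treated
sample against a matched mock (or shared background) sample.  The per-site
statistic is the differential (treated - mock); sites with background-level
differentials show no evidence of off-target cutting.  Measurements that
could not be made are carried as ND (not determined) and propagate through
the arithmetic; aggregates (mean / min / max over off-target sites) exclude
them.

The package ships the study's measured per-site indel-percentage tables
(fibroblasts and HSPC with paired mocks; transplanted-mouse tissues against
a shared spleen background) as TSV data, loadable with
:func:`load_published_tables`.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .util import round_half_away

__all__ = [
    "ND",
    "OffTargetRecord",
    "DifferentialAggregate",
    "compute_differential",
    "aggregate_differentials",
    "build_offtarget_table",
    "records_to_frame",
    "frame_to_records",
    "load_published_tables",
]

ND = None  # "not determined" sentinel; rendered as the literal "ND" in TSVs


@dataclass(frozen=True)
class OffTargetRecord:
    site_id: str
    sample: str
    pct_indels_mock: float | None
    pct_indels_zfn: float | None
    differential: float | None

    @property
    def is_on_target(self) -> bool:
        return self.site_id.strip().lower().replace("-", "").replace(" ", "") == "ontarget"


@dataclass(frozen=True)
class DifferentialAggregate:
    n_sites_used: int
    excluded_nd: int
    mean: float
    min: float
    max: float


def _check_pct(x: float | None, name: str) -> None:
    if x is None:
        return
    if not 0.0 <= x <= 100.0:
        raise ValueError(f"{name} must be a percentage in [0, 100], got {x}")


def compute_differential(mock: float | None, zfn: float | None) -> float | None:
    """treated - mock, rounded half-away-from-zero to 2 decimals; ND-propagating."""
    _check_pct(mock, "mock percentage")
    _check_pct(zfn, "treated percentage")
    if mock is None or zfn is None:
        return ND
    return round_half_away(zfn - mock, 2)


def aggregate_differentials(records: list[OffTargetRecord],
                            include_on_target: bool = False) -> DifferentialAggregate:
    """Mean/min/max of non-ND differentials, off-target sites only by default."""
    vals = [r.differential for r in records
            if (include_on_target or not r.is_on_target)]
    used = [v for v in vals if v is not None]
    if not used:
        raise ValueError("no non-ND differentials to aggregate")
    return DifferentialAggregate(
        n_sites_used=len(used),
        excluded_nd=len(vals) - len(used),
        mean=round_half_away(float(np.mean(used)), 2),
        min=float(np.min(used)),
        max=float(np.max(used)),
    )


def build_offtarget_table(mock_pcts: dict[str, float], zfn_pcts: dict[str, float],
                          sample: str = "sample",
                          site_order: list[str] | None = None
                          ) -> list[OffTargetRecord]:
    """Join mock and treated per-site indel percentages into records.

    Sites present in only one arm get ND in the missing column.  ``mock_pcts``
    and ``zfn_pcts`` map site_id -> indel percentage (e.g. the ``pct_indels``
    of a :class:`~editcall.classify.SampleSummary`).
    """
    for d in (mock_pcts, zfn_pcts):
        ids = list(d)
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate site_ids")
    sites = site_order or sorted(set(mock_pcts) | set(zfn_pcts))
    if len(sites) != len(set(sites)):
        raise ValueError("duplicate site_ids")
    out = []
    for site in sites:
        mock = mock_pcts.get(site, ND)
        zfn = zfn_pcts.get(site, ND)
        out.append(OffTargetRecord(site, sample, mock, zfn,
                                   compute_differential(mock, zfn)))
    return out


def records_to_frame(records: list[OffTargetRecord]) -> pd.DataFrame:
    def fmt(v):
        return "ND" if v is None else v
    return pd.DataFrame(
        [(r.site_id, r.sample, fmt(r.pct_indels_mock), fmt(r.pct_indels_zfn),
          fmt(r.differential)) for r in records],
        columns=["site_id", "sample", "pct_indels_mock", "pct_indels_zfn",
                 "differential"])


def frame_to_records(df: pd.DataFrame) -> list[OffTargetRecord]:
    def parse(v):
        if pd.isna(v) or (isinstance(v, str) and v.strip().upper() == "ND"):
            return ND
        return float(v)
    return [OffTargetRecord(str(row.site_id), str(row.sample),
                            parse(row.pct_indels_mock), parse(row.pct_indels_zfn),
                            parse(row.differential))
            for row in df.itertuples(index=False)]


def load_published_tables(which: str = "all") -> pd.DataFrame:
    """Bundled per-site indel-percentage tables from the modelled study.

    ``which`` selects ``"cultured"`` (fibroblasts + HSPC, paired mocks),
    ``"mice"`` (transplanted-mouse tissues against a shared spleen
    background), or ``"all"``.  The ``differential`` column holds the
    printed values; re-derive it with :func:`compute_differential` to check
    the table arithmetic.
    """
    names = {"cultured": ["offtarget_cultured.tsv"],
             "mice": ["offtarget_mice.tsv"],
             "all": ["offtarget_cultured.tsv", "offtarget_mice.tsv"]}
    if which not in names:
        raise ValueError("which must be 'cultured', 'mice' or 'all'")
    frames = []
    for name in names[which]:
        with resources.files("editcall.data").joinpath(name).open() as fh:
            frames.append(pd.read_csv(fh, sep="\t", comment="#",
                                      keep_default_na=False, na_values=[]))
    return pd.concat(frames, ignore_index=True)
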