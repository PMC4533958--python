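"""Delta-delta-CT relative quantification of qPCR validation assays.

Replicate CT values are averaged arithmetically; each sample's target
assay is normalized to the endogenous control (``delta CT = CT_target -
CT_control``), referenced to a calibrator sample (``delta delta CT``)
and expressed as ``RQ = 2 ** -ddCT``.  Mean CT above the cutoff (35
cycles) is treated as a negative measurement: the RQ is undefined and
the record is flagged instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

DEFAULT_CONTROL_ASSAY = "RNU6B"
CT_CUTOFF = 35.0


@dataclass
class CtTable:
    """Long-format CT records: (sample_id, assay_id, replicate, ct)."""

    records: pd.DataFrame
    control_assay: str = DEFAULT_CONTROL_ASSAY
    reference_sample: str | None = None

    def __post_init__(self):
        req = {"sample_id", "assay_id", "ct"}
        if not req <= set(self.records.columns):
            raise ValueError(f"CT table needs columns {sorted(req)}")
        if (self.records["ct"] <= 0).any():
            raise ValueError("CT values must be positive")


def relative_quantification(ct: CtTable, ct_cutoff: float = CT_CUTOFF,
                            per_replicate_cutoff: bool = False
                            ) -> pd.DataFrame:
    """RQ = 2^-ddCT for every (sample, target assay) pair.

    Returns one row per pair with mean CT, dCT, ddCT, RQ and flags.  The
    reference (calibrator) sample has RQ = 1 for every assay by
    construction.  The negativity cutoff applies to the replicate mean
    by default; ``per_replicate_cutoff`` flags a pair when *any*
    replicate exceeds the cutoff instead.  A sample lacking the
    endogenous control gets its assays error-flagged; a missing
    reference sample is a hard error.
    """
    rec = ct.records
    if ct.reference_sample is None:
        raise ValueError("a reference (calibrator) sample must be designated")
    if ct.reference_sample not in set(rec["sample_id"]):
        raise ValueError(f"reference sample {ct.reference_sample!r} not "
                         "present in the CT table")

    means = (rec.groupby(["sample_id", "assay_id"])["ct"]
             .agg(["mean", "max"]).rename(columns={"mean": "mean_ct"}))
    negative = (means["max"] > ct_cutoff if per_replicate_cutoff
                else means["mean_ct"] > ct_cutoff)
    means["negative"] = negative

    control = means.xs(ct.control_assay, level="assay_id")["mean_ct"] \
        if ct.control_assay in means.index.get_level_values("assay_id") \
        else pd.Series(dtype=float)

    rows = []
    targets = [a for a in rec["assay_id"].unique() if a != ct.control_assay]
    ref_dct: dict[str, float] = {}
    for assay in targets:
        sub = means.xs(assay, level="assay_id")
        if ct.reference_sample in sub.index and \
                ct.reference_sample in control.index:
            ref_dct[assay] = (sub.loc[ct.reference_sample, "mean_ct"]
                              - control.loc[ct.reference_sample])
    for assay in targets:
        sub = means.xs(assay, level="assay_id")
        for sample, row in sub.iterrows():
            mean_ct = row["mean_ct"]
            err = None
            dct = ddct = rq = np.nan
            if sample not in control.index:
                err = "missing endogenous control"
            elif assay not in ref_dct:
                err = "reference sample not measured for assay"
            else:
                dct = mean_ct - control.loc[sample]
                ddct = dct - ref_dct[assay]
                if not row["negative"]:
                    rq = 2.0 ** (-ddct)
            rows.append((sample, assay, mean_ct, dct, ddct, rq,
                         bool(row["negative"]), err))
    return pd.DataFrame(rows, columns=["sample_id", "assay_id", "mean_ct",
                                       "dct", "ddct", "rq", "negative",
                                       "error"])
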