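"""Published summary tables of the para^Shu modifier screen, as printed.

These are the screen's published inputs: male viability/fertility counts for
para^Shu with zero, one or two copies of GstS1^M26, and the GST-deficiency
penetrance table (n scored plus 1-decimal percentages and Fisher p-values
for the down-turned-wing and indented-thorax traits).  Raw per-fly data were
never published; counts are recovered from n and the printed percentages via
:func:`modscreen.phenotype_tables.reconstruct_counts`.
"""

from __future__ import annotations

import io

import pandas as pd

from .phenotype_tables import PhenotypeRecord, ViabilityRecord, reconstruct_counts

__all__ = [
    "viability_table",
    "gst_screen_table",
    "gst_screen_records",
    "SCREEN_CONTROL_LABEL",
    "SCREEN_FAMILY_SIZE",
]

# Male viability (total male progeny split into balancer and mutant classes)
# and fertility (males siring progeny out of those tested).
_VIABILITY_TSV = """\
genotype\ttotal_male\tbalancer_class\tmutant_class\tfertility_tested\tsterile\tfertile
shu\t73\t67\t6\t43\t42\t1
shu;GstS1-/+\t121\t83\t38\t45\t28\t17
shu;GstS1-/-\t145\t68\t77\t44\t27\t17
"""

# GST-deficiency screen: printed n, 1-decimal penetrances and Fisher
# p-values (strings, since some are bounds like <0.00001); asterisk = called
# significant at the Bonferroni threshold 0.05/11.
_SCREEN_TSV = """\
label\tsegment\tgenes\tn\tpct_wings\tp_wings\tpct_thorax\tp_thorax
Df(3R)Exel6164\t87B5-87B10\tGstD1-D11\t72\t95.8\t0.154\t62.5\t0.001*
Df(2R)BSC335\t55C6-55F1\tGstE1-E11\t59\t91.5\t0.741\t86.4\t0.550
Df(2R)BSC856\t60E1-60E4\tGstE12\t68\t77.9\t0.208\t83.8\t0.397
Df(2R)BSC271\t44F12-45A12\tGstE13\t67\t94.0\t0.480\t77.6\t0.0775
Df(2R)BSC273\t49F4-50A13\tGstE14\t66\t92.4\t0.517\t90.9\t1
Df(3L)BSC157\t66C12-66D6\tGstO1-O4\t150\t94.7\t0.175\t70.0\t0.0052
Df(2R)BSC132\t45F6-46B4\tGstT1-T2\t51\t68.6\t0.025\t9.8\t<0.00001*
Df(1)Exel6254\t19C4-19D1\tGstT3\t34\t91.2\t1\t94.2\t0.691
Df(1)Exel6245\t11E11-11F4\tGstT4\t26\t23.1\t<0.00001*\t80.8\t0.277
Df(3R)by10\t85D8-85E13\tGstZ1-Z2\t57\t89.5\t1\t91.2\t1
Df(2R)BSC433\t53F4-53F8\tGstS1\t56\t12.5\t<0.00001*\t35.7\t<0.00001*
No deficiency\tNA\tNA\t44\t88.6\tNA\t90.9\tNA
"""

SCREEN_CONTROL_LABEL = "No deficiency"
SCREEN_FAMILY_SIZE = 11  # deficiency rows compared against the control


def viability_table() -> list[ViabilityRecord]:
    """The published male viability/fertility counts as typed records."""
    df = pd.read_csv(io.StringIO(_VIABILITY_TSV), sep="\t")
    return [
        ViabilityRecord(
            genotype=row.genotype,
            total_male=int(row.total_male),
            balancer_class=int(row.balancer_class),
            mutant_class=int(row.mutant_class),
            fertility_tested=int(row.fertility_tested),
            sterile=int(row.sterile),
            fertile=int(row.fertile),
        )
        for row in df.itertuples()
    ]


def gst_screen_table() -> pd.DataFrame:
    """The printed GST-deficiency screen table as a DataFrame."""
    return pd.read_csv(io.StringIO(_SCREEN_TSV), sep="\t")


def gst_screen_records() -> tuple[list[PhenotypeRecord], PhenotypeRecord, pd.DataFrame]:
    """(deficiency records, control record, validation table).

    Affected counts are reconstructed from printed n and percentages; the
    validation table carries the round-trip flag per cell (one printed cell,
    GstT3 thorax, is inconsistent with every integer count out of 34 and is
    flagged False).
    """
    df = gst_screen_table()
    records: list[PhenotypeRecord] = []
    control: PhenotypeRecord | None = None
    checks = []
    for row in df.itertuples():
        counts = {}
        for trait in ("wings", "thorax"):
            pct = getattr(row, f"pct_{trait}")
            count, valid = reconstruct_counts(int(row.n), float(pct))
            counts[trait] = count
            checks.append((row.label, trait, int(row.n), float(pct), count, valid))
        rec = PhenotypeRecord(
            label=row.label,
            flies_scored=int(row.n),
            affected=counts,
            deleted_segment=row.segment,
            deleted_genes=row.genes,
        )
        if row.label == SCREEN_CONTROL_LABEL:
            control = rec
        else:
            records.append(rec)
    validation = pd.DataFrame(
        checks, columns=["label", "trait", "n", "printed_pct", "count", "roundtrip_ok"]
    )
    assert control is not None
    return records, control, validation
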