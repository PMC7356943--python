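"""Published 10-SNP adiposity GRS panel.

Risk/non-risk genotype codings of the ten obesity-related SNPs that make up
the published body-mass-index genetic risk score for the cohort this
package models.  The codings are data (a published table), not something
this package derives; the pipeline always re-learns codings from the input
cohort, and this panel exists for scoring worked examples and for users who
want to apply the published score to their own genotypes.

The published listing for rs1800592_UCP1 names CT on both sides of the
partition; the risk category is resolved here to TT, the only genotype the
listing does not name as non-risk.
"""

from __future__ import annotations

from .grs import RiskCoding

__all__ = ["published_grs_panel"]

_PANEL = [
    ("rs4731426_LEP", ("GC",), ("GG", "CC")),
    ("rs1800006_UCP3", ("AG",), ("GG", "AA")),
    ("rs1052700_PLIN1", ("TT",), ("AA", "TA")),
    ("rs1042713_ADRB2", ("AA", "AG"), ("GG",)),
    ("rs11605924_CRY2", ("CC",), ("AA", "AC")),
    ("rs1800592_UCP1", ("CC", "CT"), ("TT",)),
    ("rs2734827_UCP3", ("GG",), ("AA", "AG")),
    ("rs1440581_PPM1K", ("CC",), ("TT", "TC")),
    ("rs7799039_LEP", ("GA",), ("GG", "AA")),
    ("rs12255372_TCF7L2", ("TT",), ("GG", "GT")),
]


def published_grs_panel() -> list[RiskCoding]:
    """The ten published risk codings as :class:`RiskCoding` objects."""
    return [
        RiskCoding(snp_id, risk_genotypes=frozenset(risk),
                   nonrisk_genotypes=frozenset(nonrisk))
        for snp_id, nonrisk, risk in _PANEL
    ]
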