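"""Reference gene lists for the epilepsy risk-gene / anti-epileptic drug-target
overlap analysis.

These are the published gene lists of that analysis that are small enough to
carry verbatim: the 17 genes shared between the epilepsy risk-gene list and
the anti-epileptic drug-target list, and the 22 drug-target genes that also
appear in a 320-gene epilepsy brain co-expression network (7 of which are
themselves risk genes).  The full risk-gene (118 = 102 rare-variant + 16
common-variant), drug-target (151 genes from 47 drugs) and co-expression
(320 genes) catalogues live in external supplementary material and databases
and are represented here only by their reported sizes.
"""

from __future__ import annotations

from netoverlap.interactome import GeneSet

__all__ = [
    "RISK_TARGET_OVERLAP",
    "COEXPRESSION_TARGET_OVERLAP",
    "COEXPRESSION_RISK_GENES",
    "REPORTED_COUNTS",
    "REPORTED_MODULE_DISTANCES",
]

#: The 17 anti-epileptic drug-target genes that are also epilepsy risk genes.
RISK_TARGET_OVERLAP = GeneSet(
    "risk_target_overlap",
    (
        "CACNA1A", "CHRNA4", "CHRNA7", "GABRA1", "GABRA2", "GABRB2", "GABRG2",
        "GRIK1", "GRIN1", "GRIN2B", "KCNQ2", "KCNQ3", "SCN1A", "SCN2A",
        "SCN3A", "SCN8A", "SCN9A",
    ),
)

#: The 22 drug-target genes found in the epilepsy brain co-expression network.
COEXPRESSION_TARGET_OVERLAP = GeneSet(
    "coexpression_target_overlap",
    (
        "CACNA1C", "CACNB2", "CACNB4", "CHRNB2", "DNM1", "EEF1A2", "GABRA1",
        "GABRA3", "GABRA4", "GABRB2", "GABRB3", "GABRG2", "GRIN1", "KCNA2",
        "KCNC1", "KCNQ3", "SCN1A", "SCN4B", "SCN8A", "SOD1", "STXBP1", "SV2A",
    ),
)

#: The 7 of those 22 genes that are also epilepsy risk genes.
COEXPRESSION_RISK_GENES = GeneSet(
    "coexpression_risk_genes",
    ("GABRA1", "GABRB2", "GABRG2", "GRIN1", "KCNQ3", "SCN1A", "SCN8A"),
)

#: Reported catalogue sizes (gene counts) of the analysis.
REPORTED_COUNTS = {
    "risk_genes": 118,
    "risk_genes_rare_variant": 102,
    "risk_genes_common_variant": 16,
    "drug_targets": 151,
    "risk_target_overlap": 17,
    "coexpression_network_genes": 320,
    "ppi_network_genes": 147,
    "coexpression_target_overlap": 22,
    "coexpression_risk_genes": 7,
}

#: Reported module distances on the merged interactome (risk genes = A,
#: drug targets = B); the inputs of the separation worked example.
REPORTED_MODULE_DISTANCES = {"d_A": 1.47, "d_B": 1.44, "d_AB": 1.37}
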