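"""Published worked-example data for the primate ADH1 gene family.

These small literal tables are the published inputs the pipeline's
worked examples run on: the pairwise composite-likelihood distance matrix
among the concatenated intronic regions of the twelve human, macaque and
marmoset ADH1 paralogs (lower triangle = distances, upper = variances;
Mac_ADH1.2 was excluded from several comparisons because it is a recent
duplicate of Mac_ADH1.3 that later underwent gene conversion with
Mac_ADH1.1), and the metadata of the non-ADH reference introns screened
for molecular-clock suitability.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from paralogy.distances import DistanceMatrix

__all__ = [
    "adh1_intron_labels",
    "adh1_species_of",
    "adh1_intron_distances",
    "adh1_paralog_contrasts",
    "reference_introns",
    "speciation_split_distances",
]

_LABELS = [
    "Hum_ADH1A", "Hum_ADH1B", "Hum_ADH1C",
    "Mac_ADH1.0", "Mac_ADH1.1", "Mac_ADH1.2", "Mac_ADH1.3", "Mac_ADH1.4",
    "Cal_ADH1.1", "Cal_ADH1.2", "Cal_ADH1.3", "Cal_ADH1.4",
]

# lower-triangle rows of the published 12-paralog intronic distance matrix;
# None marks comparisons excluded in print (the Mac_ADH1.2 chimera row)
_LOWER = [
    [],
    [0.123],
    [0.143, 0.139],
    [0.134, 0.146, 0.155],
    [0.059, 0.134, 0.153, 0.143],
    [None, None, None, None, None],
    [0.139, 0.072, 0.153, 0.163, 0.151, None],
    [0.152, 0.146, 0.065, 0.164, 0.160, 0.158, 0.158],
    [0.149, 0.169, 0.171, 0.129, 0.158, 0.178, 0.187, 0.179],
    [0.127, 0.154, 0.170, 0.164, 0.132, None, 0.170, 0.179, 0.158],
    [0.146, 0.124, 0.169, 0.175, 0.157, None, 0.141, 0.176, 0.183, 0.152],
    [0.165, 0.161, 0.120, 0.184, 0.173, 0.175, 0.177, 0.127, 0.185, 0.183,
     0.172],
]


def adh1_intron_labels() -> list[str]:
    return list(_LABELS)


def adh1_species_of() -> dict[str, str]:
    return {l: l.split("_", 1)[0] for l in _LABELS}


def adh1_intron_distances() -> DistanceMatrix:
    """The published 12-paralog concatenated-intron distance matrix."""
    k = len(_LABELS)
    d = np.full((k, k), np.nan)
    np.fill_diagonal(d, 0.0)
    for i, row in enumerate(_LOWER):
        for j, val in enumerate(row):
            if val is not None:
                d[i, j] = d[j, i] = val
    return DistanceMatrix(adh1_intron_labels(), d)


def adh1_paralog_contrasts() -> dict[str, list[tuple[str, str]]]:
    """The within-species paralog and between-species ortholog pair sets
    summarised in the published averages.

    The Mac_ADH1.2 chimera is excluded from paralog averages (its printed
    distances are partial); ortholog pairs are the smallest-distance
    interspecies assignments, including the Mac_ADH1.0 pseudogene's pairing
    with Cal_ADH1.1 (its human ortholog was lost).
    """
    human = [("Hum_ADH1A", "Hum_ADH1B"), ("Hum_ADH1A", "Hum_ADH1C"),
             ("Hum_ADH1B", "Hum_ADH1C")]
    mac_members = ["Mac_ADH1.0", "Mac_ADH1.1", "Mac_ADH1.3", "Mac_ADH1.4"]
    macaque = [(a, b) for i, a in enumerate(mac_members)
               for b in mac_members[i + 1:]]
    cal_members = ["Cal_ADH1.1", "Cal_ADH1.2", "Cal_ADH1.3", "Cal_ADH1.4"]
    marmoset = [(a, b) for i, a in enumerate(cal_members)
                for b in cal_members[i + 1:]]
    hum_vs_mac = [("Hum_ADH1A", "Mac_ADH1.1"), ("Hum_ADH1B", "Mac_ADH1.3"),
                  ("Hum_ADH1C", "Mac_ADH1.4")]
    catarrhine_vs_marmoset = [
        ("Hum_ADH1A", "Cal_ADH1.2"), ("Hum_ADH1B", "Cal_ADH1.3"),
        ("Hum_ADH1C", "Cal_ADH1.4"), ("Mac_ADH1.0", "Cal_ADH1.1"),
        ("Mac_ADH1.1", "Cal_ADH1.2"), ("Mac_ADH1.3", "Cal_ADH1.3"),
        ("Mac_ADH1.4", "Cal_ADH1.4"),
    ]
    return {
        "human_paralogs": human,
        "macaque_paralogs": macaque,
        "marmoset_paralogs": marmoset,
        "all_paralogs": human + macaque + marmoset,
        "ortholog_human_vs_macaque": hum_vs_mac,
        "ortholog_catarrhine_vs_marmoset": catarrhine_vs_marmoset,
    }


def reference_introns() -> pd.DataFrame:
    """Metadata of candidate reference introns for the neutral clock panel.

    Includes the retained loci (normal GC, far from telomeres, no long
    conserved noncoding sequence) and the loci removed by the screens:
    vWF (47.1% GC, 6.2 Mbp from the telomere), SREBF2 (49.5% GC, 9.0 Mbp),
    NRAMP/SLC11a1 (47.1% GC), and five loci carrying LCNS.
    """
    rows = [
        # gene, gc%, telomere Mbp, LCNS, in mRNA db
        ("ABCA",        38.1, 30.0, False, False),
        ("CFTR_A",      37.2, 42.0, False, False),
        ("CFTR_B",      37.2, 42.0, False, False),
        ("FGA",         38.2, 35.0, False, False),
        ("ADH4_intron6", 38.5, 90.0, False, False),
        ("ADH4_intron7", 38.5, 90.0, False, False),
        ("ADH4_intron8", 38.5, 90.0, False, False),
        ("vWF",         47.1,  6.2, False, False),
        ("SREBF2",      49.5,  9.0, False, False),
        ("NRAMP",       47.1, 25.0, False, False),
        ("ERC2",        39.0, 30.0, True,  False),
        ("LUC7",        39.0, 30.0, True,  False),
        ("TTR",         39.0, 30.0, True,  False),
        ("LRPPRC_A",    39.0, 30.0, True,  False),
        ("LRPPRC_B",    39.0, 30.0, True,  False),
    ]
    return pd.DataFrame(
        rows, columns=["gene", "gc_percent", "telomere_mbp", "lcns",
                       "in_mrna"])


def speciation_split_distances() -> pd.DataFrame:
    """Ortholog intron distance summaries across the primate speciation
    splits used to bracket the duplication dates (reference-panel means)."""
    rows = [
        ("NWM_vs_catarrhine", 0.110, 0.012),
        ("OWM_vs_hominoid", 0.060, 0.008),
        ("strepsirhine_vs_haplorhine", 0.258, 0.045),
    ]
    return pd.DataFrame(rows, columns=["split", "mean", "sd"])
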