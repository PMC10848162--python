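"""Frozen per-patient table behind the 48-patient reference cohort.

The reference cohort is one feasible patient-level realization
consistent with the published cohort marginals (group sizes 15 DBA /
9 SDS / 7 DC / 2 TAR / 2 SCN / 13 undefined; 23 pancytopenic; onset
buckets 22/9/14 over 45; 10 transfusion-dependent; 40 craniofacial,
25 neurological, 23 integument, 21 growth-restricted with 8/9 in SDS
and 8/15 in DBA; complete mucocutaneous triad in 4 of 7 DC; 29 M /
19 F; two sibling pairs across 46 families; mean evaluation age 9.02).
Marginals the source tables do not constrain are filled minimally.

Columns: patient number, intended label, sex, evaluation age (years),
CBC-series start age (None = never hematologically abnormal), CBC
pattern name, HPO feature ids, then optional keyword flags.
"""

# pattern -> rows of (relative position in [0,1] across onset..span end,
# hb g/dL, mcv fL, anc /uL, platelets /uL, reticulocytes 1e9/L)
CBC_PATTERNS: dict[str, list[tuple[float, float, float, float, float, float]]] = {
    # one unremarkable CBC; no hematologic onset
    "normal": [(1.0, 12.8, 85.0, 3200.0, 260_000.0, 55.0)],
    # trilineage involvement, normocytic anemia, late count recovery
    "pan_normo": [
        (0.0, 8.8, 87.0, 1150.0, 60_000.0, 30.0),
        (0.5, 8.2, 88.0, 950.0, 45_000.0, 26.0),
        (1.0, 9.0, 86.0, 2700.0, 70_000.0, 30.0),
    ],
    "bi_anemia_thrombo": [
        (0.0, 9.2, 88.0, 2800.0, 95_000.0, 40.0),
        (1.0, 8.7, 87.0, 2600.0, 110_000.0, 38.0),
    ],
    "uni_thrombo": [
        (0.0, 13.0, 85.0, 2800.0, 95_000.0, 60.0),
        (1.0, 12.6, 86.0, 2700.0, 80_000.0, 55.0),
    ],
    "uni_anemia": [
        (0.0, 9.3, 86.0, 2900.0, 230_000.0, 40.0),
        (1.0, 9.0, 87.0, 2800.0, 220_000.0, 38.0),
    ],
    # macrocytic anemia with reticulocytopenia, other lineages spared
    "dba_anemia": [
        (0.0, 7.4, 108.0, 2700.0, 250_000.0, 8.0),
        (0.5, 6.9, 110.0, 2500.0, 260_000.0, 6.0),
        (1.0, 8.1, 107.0, 2600.0, 235_000.0, 12.0),
    ],
    "dba_pan": [
        (0.0, 7.2, 109.0, 2600.0, 260_000.0, 7.0),
        (0.5, 7.8, 110.0, 1150.0, 120_000.0, 9.0),
        (1.0, 8.4, 108.0, 2800.0, 210_000.0, 15.0),
    ],
    "sds_sev_pan": [
        (0.0, 9.0, 86.0, 350.0, 130_000.0, 28.0),
        (0.5, 8.4, 88.0, 430.0, 100_000.0, 26.0),
        (1.0, 9.6, 87.0, 2700.0, 140_000.0, 30.0),
    ],
    "sds_mild": [
        (0.0, 12.0, 84.0, 1200.0, 220_000.0, 50.0),
        (0.5, 12.4, 85.0, 1300.0, 230_000.0, 52.0),
        (1.0, 12.2, 85.0, 2600.0, 225_000.0, 50.0),
    ],
    "sds_mod": [
        (0.0, 11.8, 86.0, 800.0, 210_000.0, 45.0),
        (0.5, 12.1, 85.0, 950.0, 200_000.0, 48.0),
        (1.0, 12.0, 86.0, 2700.0, 215_000.0, 50.0),
    ],
    "sds_bi": [
        (0.0, 9.8, 88.0, 2800.0, 120_000.0, 30.0),
        (1.0, 9.5, 87.0, 2600.0, 110_000.0, 28.0),
    ],
    "tar_thrombo": [
        (0.0, 11.2, 86.0, 3200.0, 40_000.0, 45.0),
        (1.0, 11.5, 85.0, 3400.0, 55_000.0, 50.0),
    ],
    "scn_cyclic": [
        (0.0, 12.5, 84.0, 1900.0, 230_000.0, 50.0),
        (0.2, 12.3, 85.0, 300.0, 235_000.0, 48.0),
        (0.4, 12.4, 84.0, 1750.0, 228_000.0, 50.0),
        (0.6, 12.2, 85.0, 260.0, 232_000.0, 47.0),
        (0.8, 12.5, 84.0, 1650.0, 240_000.0, 50.0),
        (1.0, 12.3, 85.0, 290.0, 238_000.0, 49.0),
    ],
    # cyclic neutropenia with thrombocytopenia on two occasions
    "scn_cyclic_thrombo": [
        (0.0, 12.5, 84.0, 1900.0, 230_000.0, 50.0),
        (0.2, 12.3, 85.0, 180.0, 140_000.0, 48.0),
        (0.4, 12.4, 84.0, 1750.0, 220_000.0, 50.0),
        (0.6, 12.2, 85.0, 260.0, 135_000.0, 47.0),
        (0.8, 12.5, 84.0, 1650.0, 240_000.0, 50.0),
        (1.0, 12.3, 85.0, 300.0, 250_000.0, 49.0),
    ],
    # early severe neutropenia, recovery, then multilineage involvement
    "sds_late_pan": [
        (0.0, 11.5, 85.0, 380.0, 320_000.0, 45.0),
        (0.2, 11.2, 86.0, 300.0, 280_000.0, 42.0),
        (0.6, 10.0, 88.0, 2600.0, 140_000.0, 36.0),
        (1.0, 9.8, 87.0, 900.0, 120_000.0, 32.0),
    ],
    # infantile macrocytic anemia with reticulocytopenia, later severe
    # neutropenia without thrombocytopenia
    "dba_late_neutro": [
        (0.0, 6.8, 112.0, 2600.0, 280_000.0, 5.0),
        (0.4, 7.5, 110.0, 2550.0, 300_000.0, 10.0),
        (1.0, 8.0, 108.0, 420.0, 260_000.0, 12.0),
    ],
}

# (num, label, sex, age, series_start, pattern, features, flags)
# flags: td / tx_spread / tx_single, bm:<finding>, endogamy, consang,
#        surname, famheme, ffqt, fgr, sga, mal:<TYPE>@<age>
PATIENTS: list[tuple] = [
    # -- dyskeratosis congenita -------------------------------------------
    (1, "DC", "male", 17.01, 6.5, "pan_normo",
     ["HP:0002745", "HP:0002164", "HP:0007427", "HP:0000276", "HP:0012758"],
     ["td", "bm:hypocellular"]),
    (2, "DC", "female", 8.21, None, "normal",
     ["HP:0002745", "HP:0002164", "HP:0007427", "HP:0000414"], []),
    (3, "DC", "male", 17.11, 6.0, "pan_normo",
     ["HP:0002745", "HP:0002164", "HP:0007427", "HP:0004322", "HP:0000286",
      "HP:0012758", "HP:0002216"],
     ["td", "bm:hypocellular", "mal:MDS@14"]),
    (4, "DC", "male", 15.51, 5.5, "pan_normo",
     ["HP:0002745", "HP:0002164", "HP:0007427", "HP:0011800", "HP:0001263"],
     ["bm:hypocellular", "endogamy", "surname", "famheme", "sib:4"]),
    (5, "DC", "female", 3.11, 0.5, "pan_normo",
     ["HP:0002164", "HP:0007427", "HP:0007441", "HP:0000308", "HP:0012758"],
     ["bm:hypocellular", "endogamy", "surname", "sib:4"]),
    (6, "DC", "male", 14.71, 2.5, "bi_anemia_thrombo",
     ["HP:0007427", "HP:0004322", "HP:0012758", "HP:0000478"], ["bm:normal"]),
    (7, "DC", "female", 14.6, 5.2, "uni_thrombo",
     ["HP:0007427", "HP:0007441"], []),
    # -- Diamond-Blackfan anemia ------------------------------------------
    (8, "DBA", "male", 8.2, 0.7, "dba_pan",
     ["HP:0000414", "HP:0004322", "HP:0000957", "HP:0012758"],
     ["td", "bm:erythroid_paucity", "consang"]),
    (9, "DBA", "female", 8.0, 0.8, "dba_pan",
     ["HP:0000276", "HP:0004322", "HP:0000957", "HP:0012758"],
     ["td", "bm:hypocellular"]),
    (10, "DBA", "male", 4.1, 0.9, "dba_pan",
     ["HP:0011800", "HP:0004322", "HP:0000957", "HP:0001263"],
     ["td", "bm:hypocellular", "endogamy"]),
    (11, "DBA", "female", 2.2, 1.0, "dba_pan",
     ["HP:0000308", "HP:0004322", "HP:0000957", "HP:0012758"],
     ["td", "bm:hypocellular"]),
    (12, "DBA", "male", 2.5, 1.3, "dba_pan",
     ["HP:0000286", "HP:0004322", "HP:0000957", "HP:0012758"],
     ["td", "bm:hypocellular"]),
    (13, "DBA", "female", 2.7, 1.6, "dba_pan",
     ["HP:0000414", "HP:0004322", "HP:0000957", "HP:0012758"], ["td"]),
    (14, "DBA", "male", 5.8, 2.0, "dba_pan",
     ["HP:0000276", "HP:0004322", "HP:0000957", "HP:0001263"], ["tx_spread"]),
    (15, "DBA", "female", 6.2, 1.8, "dba_anemia",
     ["HP:0011800", "HP:0004322", "HP:0000957", "HP:0012758"], []),
    (16, "DBA", "male", 8.0, 2.5, "dba_anemia",
     ["HP:0000308", "HP:0000957", "HP:0012758"], ["endogamy"]),
    (17, "DBA", "female", 14.5, 3.0, "dba_anemia",
     ["HP:0000286", "HP:0000957", "HP:0012758"], []),
    (18, "DBA", "male", 14.6, 4.5, "dba_anemia",
     ["HP:0000414", "HP:0012758"], []),
    (19, "DBA", "female", 15.2, 6.0, "dba_anemia",
     ["HP:0000276", "HP:0012758"], []),
    (20, "DBA", "male", 10.2, 0.67, "dba_late_neutro",
     ["HP:0000276", "HP:0000414", "HP:0011800", "HP:0000308"], ["bm:normal"]),
    (21, "DBA", "female", 12.7, 7.5, "dba_anemia",
     ["HP:0011800"], ["tx_single"]),
    (22, "DBA", "male", 14.7, 9.0, "dba_anemia",
     ["HP:0000286"], []),
    # -- Shwachman-Diamond ------------------------------------------------
    (23, "SDS", "female", 4.7, None, "normal",
     ["HP:0001738", "HP:0002024", "HP:0004322", "HP:0000286"], ["ffqt"]),
    (24, "SDS", "male", 0.9, 0.6, "sds_sev_pan",
     ["HP:0001738", "HP:0012758", "HP:0007441"],
     ["ffqt", "bm:hypocellular", "endogamy", "famheme", "sib:24"]),
    (25, "SDS", "female", 3.3, 3.0, "sds_mild",
     ["HP:0004322", "HP:0005871", "HP:0045027", "HP:0000414", "HP:0012758",
      "HP:0007441"],
     ["endogamy", "sib:24"]),
    (26, "SDS", "male", 3.4, None, "normal",
     ["HP:0001738", "HP:0004322", "HP:0000308"], ["ffqt"]),
    (27, "SDS", "female", 3.9, 0.8, "sds_late_pan",
     ["HP:0002024", "HP:0004322", "HP:0000787", "HP:0000286"],
     ["ffqt", "bm:hypocellular"]),
    (28, "SDS", "male", 9.7, 0.9, "sds_sev_pan",
     ["HP:0001738", "HP:0002024", "HP:0004322", "HP:0011800", "HP:0012758",
      "HP:0007441"],
     ["ffqt", "bm:hypocellular"]),
    (29, "SDS", "female", 11.7, 4.0, "sds_mod",
     ["HP:0002024", "HP:0004322", "HP:0002240", "HP:0000276", "HP:0012758",
      "HP:0007441"],
     ["consang"]),
    (30, "SDS", "male", 4.9, 1.0, "sds_sev_pan",
     ["HP:0001738", "HP:0004322", "HP:0002240", "HP:0000414", "HP:0012758",
      "HP:0007441"],
     ["ffqt", "bm:normal"]),
    (31, "SDS", "female", 14.5, 6.5, "sds_bi",
     ["HP:0002024", "HP:0004322", "HP:0000598", "HP:0007441"], []),
    # -- thrombocytopenia with absent radii -------------------------------
    (32, "TAR", "male", 0.4, 0.1, "tar_thrombo",
     ["HP:0003974", "HP:0000414"], ["fgr"]),
    (33, "TAR", "female", 0.5, 0.2, "tar_thrombo",
     ["HP:0003974", "HP:0009601", "HP:0012758"], ["fgr", "endogamy"]),
    # -- severe congenital neutropenia ------------------------------------
    (34, "SCN", "male", 0.6, 0.3, "scn_cyclic",
     ["HP:0012758", "HP:0001627", "HP:0000119", "HP:0000308"], ["sga"]),
    (35, "SCN", "female", 6.2, 0.5, "scn_cyclic_thrombo",
     ["HP:0012758", "HP:0001627", "HP:0004322", "HP:0000276"], []),
    # -- undefined IBMFS --------------------------------------------------
    (36, "undefined_IBMFS", "male", 1.1, 0.8, "pan_normo",
     ["HP:0000414"], ["td", "bm:hypocellular", "endogamy"]),
    (37, "undefined_IBMFS", "female", 3.4, 1.2, "pan_normo",
     ["HP:0000276"], ["td", "bm:hypocellular", "consang"]),
    (38, "undefined_IBMFS", "male", 2.0, 1.7, "pan_normo",
     ["HP:0011800"], ["bm:hypocellular", "endogamy"]),
    (39, "undefined_IBMFS", "female", 10.6, 2.0, "pan_normo",
     ["HP:0000308"], ["bm:hypocellular", "mal:AML@9"]),
    (40, "undefined_IBMFS", "male", 3.9, 2.5, "pan_normo",
     ["HP:0000286"], ["bm:normal"]),
    (41, "undefined_IBMFS", "male", 7.1, 3.5, "pan_normo",
     ["HP:0000414"], ["bm:normal", "mal:MDS@6"]),
    (42, "undefined_IBMFS", "male", 17.9, 8.0, "pan_normo",
     ["HP:0002863"], ["bm:mds", "mal:MDS@8"]),
    (43, "undefined_IBMFS", "male", 15.5, 7.0, "pan_normo",
     ["HP:0001915"], ["bm:hypocellular"]),
    (44, "undefined_IBMFS", "male", 15.3, 5.0, "bi_anemia_thrombo",
     ["HP:0000276", "HP:0001510"], ["endogamy"]),
    (45, "undefined_IBMFS", "male", 17.9, 6.5, "bi_anemia_thrombo",
     ["HP:0011800", "HP:0001510"], ["tx_single"]),
    (46, "undefined_IBMFS", "male", 17.9, 5.5, "uni_thrombo",
     ["HP:0000308"], ["endogamy", "surname", "mal:solid_tumor@16"]),
    (47, "undefined_IBMFS", "male", 17.9, 6.0, "uni_anemia",
     ["HP:0000286"], ["consang"]),
    (48, "undefined_IBMFS", "male", 17.9, 5.2, "uni_thrombo",
     [], []),
]
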