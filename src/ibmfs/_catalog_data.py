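"""Built-in mini-HPO term table and rule groups.

The catalog is deliberately small: it carries only the terms the triage
rules reference and the parent links needed for descendant matching
(e.g. developmental delay counts toward the neurological-abnormality
root). It is not a substitute for the full Human Phenotype Ontology;
full-ontology reasoning is out of scope.
"""

# term_id -> (label, parent term_ids)
TERMS: dict[str, tuple[str, tuple[str, ...]]] = {
    "HP:0000118": ("Phenotypic abnormality", ()),
    # -- hematologic -------------------------------------------------------
    "HP:0001871": ("Abnormality of blood and blood-forming tissues", ("HP:0000118",)),
    "HP:0001903": ("Anemia", ("HP:0001871",)),
    "HP:0001972": ("Macrocytic anemia", ("HP:0001903",)),
    "HP:0001896": ("Reticulocytopenia", ("HP:0001871",)),
    "HP:0001873": ("Thrombocytopenia", ("HP:0001871",)),
    "HP:0001875": ("Neutropenia", ("HP:0001871",)),
    "HP:0040289": ("Cyclic neutropenia", ("HP:0001875",)),
    "HP:0001882": ("Leukopenia", ("HP:0001871",)),
    "HP:0001876": ("Pancytopenia", ("HP:0001871",)),
    "HP:0001915": ("Aplastic anemia", ("HP:0001871",)),
    "HP:0002863": ("Myelodysplasia", ("HP:0001871",)),
    "HP:0004808": ("Acute myeloid leukemia", ("HP:0001871",)),
    # -- organ-system roots ------------------------------------------------
    "HP:0001999": ("Abnormal facial shape", ("HP:0000118",)),
    "HP:0000707": ("Abnormality of the nervous system", ("HP:0000118",)),
    "HP:0001574": ("Abnormality of the integument", ("HP:0000118",)),
    "HP:0001510": ("Growth delay", ("HP:0000118",)),
    "HP:0011024": ("Abnormality of the gastrointestinal tract", ("HP:0000118",)),
    "HP:0001732": ("Abnormality of the pancreas", ("HP:0000118",)),
    "HP:0000924": ("Abnormality of the skeletal system", ("HP:0000118",)),
    "HP:0001627": ("Congenital heart defect", ("HP:0000118",)),
    "HP:0000119": ("Abnormality of the genitourinary system", ("HP:0000118",)),
    "HP:0000478": ("Abnormality of the eye", ("HP:0000118",)),
    "HP:0000598": ("Abnormality of the ear", ("HP:0000118",)),
    "HP:0001392": ("Abnormality of the liver", ("HP:0000118",)),
    "HP:0002088": ("Abnormal lung morphology", ("HP:0000118",)),
    "HP:0000153": ("Abnormality of the mouth", ("HP:0000118",)),
    "HP:0000464": ("Abnormality of the neck", ("HP:0000118",)),
    "HP:0002817": ("Abnormality of the upper limb", ("HP:0000924",)),
    # -- dyskeratosis congenita --------------------------------------------
    "HP:0002745": ("Oral leukoplakia", ("HP:0000153",)),
    "HP:0001597": ("Abnormality of the nail", ("HP:0001574",)),
    "HP:0002164": ("Nail dysplasia", ("HP:0001597",)),
    "HP:0007427": ("Reticulated skin pigmentation", ("HP:0001574",)),
    "HP:0007441": ("Hyper- and hypopigmented skin macules", ("HP:0001574",)),
    "HP:0000957": ("Cafe-au-lait macule", ("HP:0007441",)),
    "HP:0002216": ("Premature graying of the hair", ("HP:0001574",)),
    "HP:0002206": ("Pulmonary fibrosis", ("HP:0002088",)),
    # -- growth ------------------------------------------------------------
    "HP:0004322": ("Short stature", ("HP:0001510",)),
    # -- Shwachman-Diamond -------------------------------------------------
    "HP:0001738": ("Exocrine pancreatic insufficiency", ("HP:0001732",)),
    "HP:0002024": ("Malabsorption", ("HP:0011024",)),
    "HP:0005871": ("Metaphyseal chondrodysplasia", ("HP:0000924",)),
    "HP:0045027": ("Abnormality of the thoracic cavity", ("HP:0000924",)),
    "HP:0002240": ("Hepatomegaly", ("HP:0001392",)),
    # -- craniofacial descendants ------------------------------------------
    "HP:0000252": ("Microcephaly", ("HP:0001999",)),
    "HP:0000276": ("Long face", ("HP:0001999",)),
    "HP:0000414": ("Bulbous nose", ("HP:0001999",)),
    "HP:0011800": ("Midface retrusion", ("HP:0001999",)),
    "HP:0000308": ("Microretrognathia", ("HP:0001999",)),
    "HP:0000286": ("Epicanthus", ("HP:0001999",)),
    # -- neurological descendants ------------------------------------------
    "HP:0012758": ("Neurodevelopmental delay", ("HP:0000707",)),
    "HP:0001263": ("Global developmental delay", ("HP:0012758",)),
    "HP:0002011": ("Morphological central nervous system abnormality", ("HP:0000707",)),
    "HP:0100543": ("Cognitive impairment", ("HP:0000707",)),
    "HP:0001250": ("Seizure", ("HP:0000707",)),
    "HP:0000238": ("Hydrocephalus", ("HP:0000707",)),
    # -- limb / TAR --------------------------------------------------------
    "HP:0410049": ("Abnormal radial ray morphology", ("HP:0002817",)),
    "HP:0003974": ("Absent radius", ("HP:0410049",)),
    "HP:0009601": ("Aplasia/hypoplasia of the thumb", ("HP:0410049",)),
    "HP:0009777": ("Absent thumb", ("HP:0009601",)),
    "HP:0000077": ("Abnormality of the kidney", ("HP:0000119",)),
    "HP:0000787": ("Nephrolithiasis", ("HP:0000077",)),
    # -- VACTERL extras ----------------------------------------------------
    "HP:0000925": ("Abnormality of the vertebral column", ("HP:0000924",)),
    "HP:0002023": ("Anal atresia", ("HP:0011024",)),
    "HP:0002575": ("Tracheoesophageal fistula", ("HP:0011024",)),
    "HP:0000568": ("Microphthalmia", ("HP:0000478",)),
}

# rule-facing groups; every member must resolve in TERMS
GROUPS: dict[str, frozenset[str]] = {
    "dc_triad": frozenset({"HP:0002745", "HP:0002164", "HP:0007427"}),
    "dc_supportive": frozenset({"HP:0002216", "HP:0004322", "HP:0000478", "HP:0002206"}),
    "sds_associated": frozenset({
        "HP:0001738", "HP:0002024", "HP:0004322", "HP:0005871",
        "HP:0045027", "HP:0001627", "HP:0000598", "HP:0002240",
    }),
    "dba_minor": frozenset({
        "HP:0004322", "HP:0000252", "HP:0001999", "HP:0000464",
        "HP:0002817", "HP:0001627", "HP:0000119",
    }),
    "scn_associated": frozenset({"HP:0004322", "HP:0001627", "HP:0000119"}),
    "tar_radial": frozenset({"HP:0410049"}),
    "tar_supportive": frozenset({"HP:0001627", "HP:0000077"}),
    "thumb_absence": frozenset({"HP:0009777"}),
    "vacterl_h": frozenset({
        "HP:0000925", "HP:0002023", "HP:0001627", "HP:0002575",
        "HP:0000077", "HP:0002817", "HP:0000238",
    }),
    "phenos": frozenset({
        "HP:0007441", "HP:0000252", "HP:0000478",
        "HP:0000707", "HP:0000598", "HP:0004322",
    }),
    "craniofacial": frozenset({"HP:0001999"}),
    "neurological": frozenset({"HP:0000707"}),
    "integument": frozenset({"HP:0001574"}),
    "growth": frozenset({"HP:0001510"}),
    "hematologic": frozenset({"HP:0001871"}),
}

# organ-system partition used when counting distinct non-hematological
# manifestations for eligibility
ORGAN_SYSTEMS: dict[str, str] = {
    "craniofacial": "HP:0001999",
    "neurological": "HP:0000707",
    "integument": "HP:0001574",
    "growth": "HP:0001510",
    "gastrointestinal": "HP:0011024",
    "pancreatic": "HP:0001732",
    "skeletal": "HP:0000924",
    "cardiac": "HP:0001627",
    "genitourinary": "HP:0000119",
    "ocular": "HP:0000478",
    "ear": "HP:0000598",
    "liver": "HP:0001392",
    "respiratory": "HP:0002088",
    "oral": "HP:0000153",
    "neck": "HP:0000464",
}

# explicit equivalences for group matching: the generic nail-abnormality
# code is accepted for the nail element of the mucocutaneous triad even
# though it is the catalog *parent* of nail dysplasia
GROUP_EQUIVALENTS: dict[str, frozenset[str]] = {
    "HP:0002164": frozenset({"HP:0001597"}),
}

# groups a user-supplied catalog config may extend but never shrink
PROTECTED_GROUPS = (
    "dc_triad", "dc_supportive", "sds_associated", "dba_minor",
    "scn_associated", "tar_radial", "tar_supportive", "thumb_absence",
    "vacterl_h", "phenos",
)
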