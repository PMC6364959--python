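"""Sentence templates used to assemble synthetic clinical notes.

Every template is pre-normalized (lower case, single spaces) so that a
noise-free note is a verbatim concatenation of templates. Each template
carries a known gold label with respect to the depression lexicon.
"""

AFFIRMED_TEMPLATES = (
    "major depressive disorder, recurrent episode, moderate",
    "stress and depression, need to continue medication",
    "patient stating more depression recently, was at behavioral facility and is now more paranoid",
    "patient reports worsening depression and poor sleep",
    "history of major depression, currently followed by psychiatry",
    "screening positive for depressive symptoms at this visit",
    "depressed mood noted during the interview",
)

NEGATED_TEMPLATES = (
    "patient had no preinjury mental health issues or depression",
    "anxiety was situational, currently no symptoms of depression",
    "denies depression or anxiety",
    "no evidence of major depressive disorder",
    "patient is without depression at this time",
    "negative for depression and suicidal ideation",
)

# Decoy sentences: the depression token appears only in an irrelevant
# sense covered by an exclusion pattern, so gold is NoMention.
DECOY_TEMPLATES = (
    "ecg shows st depression in leads ii",
    "imaging reveals depression fracture of the skull",
    "st segment depression noted on stress test",
    "depression of the tibial plateau noted on imaging",
    "monitor for respiratory depression after opioid administration",
)

NEUTRAL_TEMPLATES = (
    "patient is doing well",
    "vital signs stable and afebrile",
    "wound healing appropriately",
    "ambulating independently in the hallway",
    "plan to continue current medications",
    "follow up in clinic in two weeks",
    "pain controlled with current regimen",
    "incision clean dry and intact",
    "tolerating a regular diet",
    "no acute distress observed on exam",
)

# Affirmed with respect to the SSRI lexicon; NoMention for depression.
SSRI_MENTION_TEMPLATES = (
    "continue sertraline 50 mg daily",
    "taking fluoxetine 20 mg each morning",
    "refilled escitalopram at current dose",
)

SSRI_NEGATED_TEMPLATES = (
    "discontinued prozac years ago, denies current use",
    "stopped sertraline due to side effects",
)

NOTE_TYPES = ("History & Physical", "progress", "discharge summary")

GOLD_BY_TEMPLATE = {}
for _t in AFFIRMED_TEMPLATES:
    GOLD_BY_TEMPLATE[_t] = "Affirmed"
for _t in NEGATED_TEMPLATES:
    GOLD_BY_TEMPLATE[_t] = "Negated"
for _t in (
    DECOY_TEMPLATES
    + NEUTRAL_TEMPLATES
    + SSRI_MENTION_TEMPLATES
    + SSRI_NEGATED_TEMPLATES
):
    GOLD_BY_TEMPLATE[_t] = "NoMention"

ALL_TEMPLATES = tuple(GOLD_BY_TEMPLATE)
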