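"""Bundled word lists: stopwords, a small lemma lexicon, default class names,
the default crisis keyword list, and a seed sentiment lexicon.

All lists are deliberately small, plain-Python and editable; every consumer
accepts a user-supplied replacement (CSV or config) and these serve only as
download-free defaults.
"""

from __future__ import annotations

# Default topic/class names for the ten-class crisis taxonomy used when no
# name table is configured.  Index = topic id.
DEFAULT_TOPIC_NAMES: tuple[str, ...] = (
    "Conspiracy Theory",
    "COVID-19 information",
    "COVID-19 statistics",
    "Economics",
    "Fake Treatment",
    "Governmental Measures",
    "Politics",
    "Public health measures",
    "Stocking Up",
    "Vaccine/Cure",
)

# Default collection keywords (stored lowercase, without '#').
DEFAULT_KEYWORDS: tuple[str, ...] = (
    "vaccine",
    "pfizer",
    "moderna",
    "astrazeneca",
    "sputnik",
    "sinopharm",
    "coronavirus",
    "coronavirusoutbreak",
    "coronaviruspandemic",
    "covid19",
    "covid_19",
    "epitwitter",
    "ihavecorona",
    "stayhomestaysafe",
    "testtraceisolate",
)

# A compact English stopword list (function words + common contractions).
STOPWORDS: frozenset[str] = frozenset("""
a about above after again against all am an and any are aren't as at be
because been before being below between both but by can can't cannot could
couldn't did didn't do does doesn't doing don't down during each few for from
further had hadn't has hasn't have haven't having he he'd he'll he's her here
here's hers herself him himself his how how's i i'd i'll i'm i've if in into
is isn't it it's its itself let's me more most mustn't my myself no nor not of
off on once only or other ought our ours ourselves out over own same shan't
she she'd she'll she's should shouldn't so some such than that that's the
their theirs them themselves then there there's these they they'd they'll
they're they've this those through to too under until up very was wasn't we
we'd we'll we're we've were weren't what what's when when's where where's
which while who who's whom why why's with won't would wouldn't you you'd
you'll you're you've your yours yourself yourselves
""".split())

# Surface form -> (lemma, part of speech).  POS tags: noun / verb / adjective /
# adverb.  Tokens absent from the lexicon default to (token, "noun").
LEMMA_LEXICON: dict[str, tuple[str, str]] = {
    "vaccines": ("vaccine", "noun"),
    "vaccinated": ("vaccinate", "verb"),
    "vaccinations": ("vaccination", "noun"),
    "vaccinating": ("vaccinate", "verb"),
    "viruses": ("virus", "noun"),
    "masks": ("mask", "noun"),
    "cases": ("case", "noun"),
    "deaths": ("death", "noun"),
    "died": ("die", "verb"),
    "dying": ("die", "verb"),
    "works": ("work", "verb"),
    "working": ("work", "verb"),
    "worked": ("work", "verb"),
    "closed": ("close", "verb"),
    "closures": ("closure", "noun"),
    "restrictions": ("restriction", "noun"),
    "lockdowns": ("lockdown", "noun"),
    "hospitals": ("hospital", "noun"),
    "doctors": ("doctor", "noun"),
    "nurses": ("nurse", "noun"),
    "tested": ("test", "verb"),
    "testing": ("test", "verb"),
    "tests": ("test", "noun"),
    "spreading": ("spread", "verb"),
    "spreads": ("spread", "verb"),
    "infections": ("infection", "noun"),
    "infected": ("infect", "verb"),
    "recovered": ("recover", "verb"),
    "recoveries": ("recovery", "noun"),
    "economies": ("economy", "noun"),
    "economic": ("economic", "adjective"),
    "jobs": ("job", "noun"),
    "schools": ("school", "noun"),
    "quickly": ("quickly", "adverb"),
    "slowly": ("slowly", "adverb"),
    "really": ("really", "adverb"),
    "very": ("very", "adverb"),
    "safely": ("safely", "adverb"),
    "better": ("good", "adjective"),
    "worse": ("bad", "adjective"),
    "higher": ("high", "adjective"),
    "lower": ("low", "adjective"),
    "says": ("say", "verb"),
    "said": ("say", "verb"),
    "goes": ("go", "verb"),
    "going": ("go", "verb"),
    "went": ("go", "verb"),
    "getting": ("get", "verb"),
    "got": ("get", "verb"),
    "taking": ("take", "verb"),
    "taken": ("take", "verb"),
    "took": ("take", "verb"),
    "made": ("make", "verb"),
    "making": ("make", "verb"),
    "children": ("child", "noun"),
    "people": ("people", "noun"),
    "countries": ("country", "noun"),
    "governments": ("government", "noun"),
    "measures": ("measure", "noun"),
    "numbers": ("number", "noun"),
    "variants": ("variant", "noun"),
    "doses": ("dose", "noun"),
}

# Seed sentiment lexicon: term -> +1 (positive) or -1 (negative).
SENTIMENT_LEXICON: dict[str, int] = {
    "good": +1, "great": +1, "hope": +1, "hopeful": +1, "safe": +1,
    "effective": +1, "recovery": +1, "recover": +1, "success": +1,
    "successful": +1, "happy": +1, "relief": +1, "protect": +1,
    "protection": +1, "improve": +1, "improvement": +1, "positive": +1,
    "trust": +1, "win": +1, "better": +1, "best": +1, "love": +1,
    "thankful": +1, "grateful": +1, "optimistic": +1, "immunity": +1,
    "bad": -1, "terrible": -1, "fear": -1, "afraid": -1, "scared": -1,
    "death": -1, "die": -1, "dangerous": -1, "danger": -1, "fail": -1,
    "failure": -1, "sad": -1, "angry": -1, "anger": -1, "worried": -1,
    "worry": -1, "negative": -1, "distrust": -1, "lose": -1, "loss": -1,
    "worse": -1, "worst": -1, "hate": -1, "crisis": -1, "panic": -1,
    "hoax": -1, "scam": -1,
}
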