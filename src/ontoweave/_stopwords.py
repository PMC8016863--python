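"""Built-in English stopword list, v1 (pinned for reproducibility).

A fixed, versioned list shipped with the package so terminology preprocessing
is identical across machines; override with any file of one word per line.
"""

STOPWORDS_VERSION = "1"

ENGLISH_STOPWORDS = frozenset(
    """
a about above after again against all am an and any are as at be because been
before being below between both but by can cannot could did do does doing down
during each few for from further had has have having he her here hers herself
him himself his how i if in into is it its itself just me more most my myself
no nor not now of off on once only or other our ours ourselves out over own
same she should so some such than that the their theirs them themselves then
there these they this those through to too under until up very was we were
what when where which while who whom why will with you your yours yourself
yourselves
""".split()
)


def load_stopwords(path=None) -> frozenset:
    """Return the pinned built-in list, or the contents of ``path`` if given."""
    if path is None:
        return ENGLISH_STOPWORDS
    with open(path, encoding="utf-8") as fh:
        return frozenset(w.strip().lower() for w in fh if w.strip())
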