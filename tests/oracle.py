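"""Brute-force cell-counting oracle, independent of the package internals.

Works on plain lists of (study, sample, attribute, source, level) tuples and
counts cells with explicit loops; used to cross-check the pandas-based
completeness and source-comparison statistics.
"""

from fractions import Fraction

AVAILABLE = ("sample_level", "experiment_level")


def pooled_availability(cells, source):
    num = den = 0
    for study, sample, attr, src, level in cells:
        if src != source or level == "not_applicable":
            continue
        den += 1
        if level in AVAILABLE:
            num += 1
    return Fraction(num, den) if den else Fraction(0)


def per_attribute_availability(cells, source):
    counts = {}
    for study, sample, attr, src, level in cells:
        if src != source or level == "not_applicable":
            continue
        num, den = counts.get(attr, (0, 0))
        counts[attr] = (num + (level in AVAILABLE), den + 1)
    return {a: Fraction(n, d) for a, (n, d) in counts.items()}


def study_brackets(cells, source):
    shared = {}
    for study, sample, attr, src, level in cells:
        if src != source or level == "not_applicable":
            continue
        shared.setdefault(study, set())
        if level in AVAILABLE:
            shared[study].add(attr)
    return {study: 20 * len(attrs) for study, attrs in shared.items()}


def either_availability(cells):
    best = {}
    for study, sample, attr, src, level in cells:
        key = (study, sample, attr)
        prev = best.get(key)
        rank = {"sample_level": 3, "experiment_level": 2, "missing": 1,
                "not_applicable": 0}
        if prev is None or rank[level] > rank[prev]:
            best[key] = level
    num = den = 0
    for level in best.values():
        if level == "not_applicable":
            continue
        den += 1
        num += level in AVAILABLE
    return Fraction(num, den) if den else Fraction(0)


def source_categories(cells):
    repo, text = {}, {}
    for study, sample, attr, src, level in cells:
        key = (study, sample, attr)
        (repo if src == "repository" else text)[key] = level
    out = {}
    for key in repo:
        r, t = repo[key], text[key]
        if r == "not_applicable":
            out[key] = "not_applicable"
        elif r in AVAILABLE and t in AVAILABLE:
            out[key] = "both"
        elif r in AVAILABLE:
            out[key] = "repo_only"
        elif t in AVAILABLE:
            out[key] = "text_only"
        else:
            out[key] = "neither"
    return out
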