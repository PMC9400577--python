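"""Word stemming.

Node identity in a forma mentis network is a stem, not a surface form, so the
whole pipeline (corpus text, lexicon keys, synonym pairs, query targets) must
pass through one consistent stemmer.  The default is the Snowball stemming
algorithm for Italian, implemented here from the published algorithm
definition; Italian is the language of the target stems this package is built
around ("vaccin", "astrazenec", "mort", "trombos").

Synthetic corpora emit tokens that are already stems, so they use the
:func:`identity_stemmer` instead.
"""

from __future__ import annotations

from typing import Callable

Stemmer = Callable[[str], str]

_VOWELS = set("aeiouàèìòù")

_ACUTE_TO_GRAVE = str.maketrans("áéíóú", "àèìòù")

_PRONOUNS = (
    "gliela", "gliele", "glieli", "glielo", "gliene",
    "sene", "mela", "mele", "meli", "melo", "mene",
    "tela", "tele", "teli", "telo", "tene",
    "cela", "cele", "celi", "celo", "cene",
    "vela", "vele", "veli", "velo", "vene",
    "gli", "ci", "la", "le", "li", "lo", "mi", "ne", "si", "ti", "vi",
)

# step-1 standard suffixes: (suffix, region, replacement); longest match wins
_STEP1 = sorted(
    [
        ("amente", "r1", ""),
        ("atrice", "r2", ""), ("atrici", "r2", ""),
        ("azione", "r2", ""), ("azioni", "r2", ""),
        ("uzione", "r2", "u"), ("uzioni", "r2", "u"),
        ("usione", "r2", "u"), ("usioni", "r2", "u"),
        ("amento", "rv", ""), ("amenti", "rv", ""),
        ("imento", "rv", ""), ("imenti", "rv", ""),
        ("atore", "r2", ""), ("atori", "r2", ""),
        ("abile", "r2", ""), ("abili", "r2", ""),
        ("ibile", "r2", ""), ("ibili", "r2", ""),
        ("logia", "r2", "log"), ("logie", "r2", "log"),
        ("mente", "r2", ""),
        ("anza", "r2", ""), ("anze", "r2", ""),
        ("iche", "r2", ""), ("ichi", "r2", ""),
        ("ismo", "r2", ""), ("ismi", "r2", ""),
        ("ista", "r2", ""), ("iste", "r2", ""), ("isti", "r2", ""),
        ("istà", "r2", ""), ("istè", "r2", ""), ("istì", "r2", ""),
        ("ante", "r2", ""), ("anti", "r2", ""),
        ("enza", "r2", "ente"), ("enze", "r2", "ente"),
        ("ico", "r2", ""), ("ici", "r2", ""), ("ica", "r2", ""),
        ("ice", "r2", ""),
        ("oso", "r2", ""), ("osi", "r2", ""), ("osa", "r2", ""),
        ("ose", "r2", ""),
        ("ità", "r2", ""),
        ("ivo", "r2", ""), ("ivi", "r2", ""), ("iva", "r2", ""),
        ("ive", "r2", ""),
    ],
    key=lambda t: -len(t[0]),
)

_STEP2 = sorted(
    [
        "erebbero", "irebbero", "assero", "assimo", "eranno", "erebbe",
        "eremmo", "ereste", "eresti", "essero", "iranno", "irebbe", "iremmo",
        "ireste", "iresti", "iscano", "iscono", "issero", "arono", "avamo",
        "avano", "avate", "eremo", "erete", "erono", "evamo", "evano",
        "evate", "iremo", "irete", "irono", "ivamo", "ivano", "ivate",
        "ammo", "ando", "asse", "assi", "emmo", "enda", "ende", "endi",
        "endo", "erai", "erei", "iamo", "immo", "irai", "irei", "isca",
        "isce", "isci", "isco", "ano", "are", "ata", "ate", "ati", "ato",
        "ava", "avi", "avo", "erà", "ere", "erò", "ete", "eva", "evi",
        "evo", "irà", "ire", "irò", "ita", "ite", "iti", "ito", "iva",
        "ivi", "ivo", "ono", "uta", "ute", "uti", "uto", "ar", "er", "ir",
    ],
    key=len,
    reverse=True,
)


def _mark(word: str) -> str:
    """Prelude: normalise accents and mark vocalic i/u acting as consonants."""
    word = word.translate(_ACUTE_TO_GRAVE)
    chars = list(word)
    for k in range(1, len(chars)):
        if chars[k] == "u" and chars[k - 1] == "q":
            chars[k] = "U"
    for k in range(1, len(chars) - 1):
        if chars[k] in "iu" and chars[k - 1] in _VOWELS and chars[k + 1] in _VOWELS:
            chars[k] = chars[k].upper()
    return "".join(chars)


def _is_vowel(c: str) -> bool:
    return c in _VOWELS


def _rv_start(word: str) -> int:
    if len(word) < 3:
        return len(word)
    if not _is_vowel(word[1]):
        # consonant in second position: after the next vowel
        for k in range(2, len(word)):
            if _is_vowel(word[k]):
                return k + 1
        return len(word)
    if _is_vowel(word[0]) and _is_vowel(word[1]):
        # two initial vowels: after the next consonant
        for k in range(2, len(word)):
            if not _is_vowel(word[k]):
                return k + 1
        return len(word)
    return 3  # consonant-vowel start


def _r_start(word: str, begin: int) -> int:
    """Region after the first consonant following a vowel, scanning from begin."""
    for k in range(begin, len(word) - 1):
        if _is_vowel(word[k]) and not _is_vowel(word[k + 1]):
            return k + 2
    return len(word)


def _in_region(word: str, suffix_len: int, region_start: int) -> bool:
    return len(word) - suffix_len >= region_start


def italian_stem(word: str) -> str:
    """Stem one Italian word (lowercased) with the Snowball algorithm."""
    word = _mark(word.lower())
    rv = _rv_start(word)
    r1 = _r_start(word, 0)
    r2 = _r_start(word, r1)

    # step 0: attached pronouns after a gerund or infinitive marker;
    # the whole lead+pronoun pattern must lie in RV
    for pron in _PRONOUNS:  # list is longest-first
        if not word.endswith(pron):
            continue
        base = len(word) - len(pron)
        for lead, repl in (("ando", ""), ("endo", ""), ("ar", "e"),
                           ("er", "e"), ("ir", "e")):
            start = base - len(lead)
            if start >= 0 and word[start:base] == lead and start >= rv:
                word = word[:base] + repl
                break
        break

    changed = False
    # step 1: standard suffixes (longest match)
    for suf, region, repl in _STEP1:
        if not word.endswith(suf):
            continue
        start = {"rv": rv, "r1": r1, "r2": r2}[region]
        if not _in_region(word, len(suf), start):
            break
        stem = word[:-len(suf)] + repl
        if suf == "amente":
            # secondary endings inside R2
            if stem.endswith("iv") and _in_region(stem, 2, r2):
                stem = stem[:-2]
                if stem.endswith("at") and _in_region(stem, 2, r2):
                    stem = stem[:-2]
            else:
                for sec in ("os", "ic", "abil"):
                    if stem.endswith(sec) and _in_region(stem, len(sec), r2):
                        stem = stem[:-len(sec)]
                        break
        elif suf in ("azione", "azioni", "atore", "atori", "ità"):
            extras = ("ic",) if suf.startswith("a") else ("abil", "ic", "iv")
            for sec in extras:
                if stem.endswith(sec) and _in_region(stem, len(sec), r2):
                    stem = stem[:-len(sec)]
                    break
        elif suf in ("ivo", "ivi", "iva", "ive"):
            if stem.endswith("at") and _in_region(stem, 2, r2):
                stem = stem[:-2]
                if stem.endswith("ic") and _in_region(stem, 2, r2):
                    stem = stem[:-2]
        word = stem
        changed = True
        break

    # step 2: verb suffixes, only if step 1 removed nothing
    if not changed:
        for suf in _STEP2:
            if word.endswith(suf) and _in_region(word, len(suf), rv):
                word = word[:-len(suf)]
                break

    # step 3a: final vowel (and a preceding i), within RV
    if word and word[-1] in "aeioàèìò" and _in_region(word, 1, rv):
        word = word[:-1]
        if word and word[-1] == "i" and _in_region(word, 1, rv):
            word = word[:-1]
    # step 3b
    if (word.endswith("ch") or word.endswith("gh")) and _in_region(word, 1, rv):
        word = word[:-1]

    return word.replace("I", "i").replace("U", "u")


def identity_stemmer(word: str) -> str:
    """Lowercase pass-through, for corpora whose tokens are already stems."""
    return word.lower()


_STEMMERS: dict[str, Stemmer] = {
    "italian": italian_stem,
    "identity": identity_stemmer,
}


def get_stemmer(name: str) -> Stemmer:
    try:
        return _STEMMERS[name]
    except KeyError:
        raise KeyError(
            f"unknown stemmer {name!r}; available: {sorted(_STEMMERS)}"
        ) from None
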