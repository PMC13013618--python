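"""A compact rule-based English lemmatizer.

Maps inflected forms to dictionary heads well enough for bag-of-words topic
modeling: plural nouns, -ing / -ed verb forms (with consonant-doubling and
silent-e restoration) and a table of frequent irregulars.  It is intentionally
conservative -- a token it cannot analyse is returned unchanged, which for
topic modeling merely leaves an occasional inflected surface form in the
vocabulary.
"""

from __future__ import annotations

__all__ = ["lemmatize"]

# Frequent irregular verbs / nouns / comparatives.
_IRREGULAR = {
    "am": "be", "is": "be", "are": "be", "was": "be", "were": "be", "been": "be",
    "being": "be", "has": "have", "had": "have", "having": "have", "does": "do",
    "did": "do", "done": "do", "doing": "do", "goes": "go", "went": "go",
    "gone": "go", "going": "go", "said": "say", "says": "say", "made": "make",
    "making": "make", "took": "take", "taken": "take", "taking": "take",
    "came": "come", "coming": "come", "got": "get", "gotten": "get",
    "getting": "get", "gave": "give", "given": "give", "giving": "give",
    "knew": "know", "known": "know", "saw": "see", "seen": "see", "thought":
    "think", "found": "find", "told": "tell", "became": "become", "began":
    "begin", "begun": "begin", "held": "hold", "kept": "keep", "left": "leave",
    "meant": "mean", "put": "put", "ran": "run", "running": "run", "brought":
    "bring", "wrote": "write", "written": "write", "writing": "write",
    "spoke": "speak", "spoken": "speak", "stood": "stand", "understood":
    "understand", "lost": "lose", "felt": "feel", "built": "build", "sent":
    "send", "spent": "spend", "fell": "fall", "fallen": "fall", "drew": "draw",
    "drawn": "draw", "grew": "grow", "grown": "grow", "threw": "throw",
    "thrown": "throw", "shown": "show", "heard": "hear", "met": "meet",
    "paid": "pay", "read": "read", "led": "lead", "lay": "lie", "lain": "lie",
    "men": "man", "women": "woman", "children": "child", "people": "person",
    "feet": "foot", "teeth": "tooth", "mice": "mouse", "geese": "goose",
    "better": "good", "best": "good", "worse": "bad", "worst": "bad",
    "larger": "large", "largest": "large", "bigger": "big", "biggest": "big",
    "nuclei": "nucleus", "radii": "radius", "phenomena": "phenomenon",
    "data": "datum", "forces": "force", "stars": "star",
}

# Words that look inflected but are not (or whose stem would be wrong).
_FROZEN = {
    "this", "his", "its", "was", "as", "us", "is", "yes", "thus", "plus",
    "gas", "physics", "mass", "less", "pass", "class", "process", "across",
    "perhaps", "always", "series", "species", "analysis", "basis", "lens",
    "universe", "during", "thing", "something", "anything", "everything",
    "nothing", "morning", "evening", "ring", "string", "spring", "king",
    "wing", "sing", "bring", "being", "sting", "energy",
}

_VOWELS = set("aeiou")
_NO_UNDOUBLE = {"ll", "ss", "ee", "oo", "zz", "ff"}

# Small whitelist for restoring a silent 'e' after stripping -ing / -ed.
_E_RESTORE = {
    "mak", "tak", "com", "giv", "hav", "mov", "us", "caus", "chang", "creat",
    "produc", "increas", "decreas", "describ", "defin", "believ", "receiv",
    "liv", "lov", "not", "stat", "rotat", "generat", "accelerat", "observ",
    "measur", "releas", "fus", "collaps", "combin", "compar", "sav", "shar",
    "writ", "rang", "merg", "escap", "explod", "radiat", "orbit",
}


def _strip_plural(word: str) -> str:
    if word.endswith("ies") and len(word) > 4:
        return word[:-3] + "y"
    if word.endswith(("ches", "shes", "xes", "zes", "sses")):
        return word[:-2]
    if word.endswith("oes") and len(word) > 4:
        return word[:-2]
    if word.endswith("s") and not word.endswith(("ss", "us", "is")):
        return word[:-1]
    return word


def _fix_stem(stem: str) -> str:
    # undouble final consonant (running -> run) unless the doubling is lexical
    if len(stem) > 2 and stem[-1] == stem[-2] and stem[-2:] not in _NO_UNDOUBLE:
        return stem[:-1]
    if stem in _E_RESTORE:
        return stem + "e"
    return stem


def lemmatize(word: str) -> str:
    """Return the lemma of a lower-cased alphabetic token."""
    if word in _FROZEN:
        return word
    if word in _IRREGULAR:
        return _IRREGULAR[word]
    if word.endswith("ing") and len(word) > 5:
        stem = _fix_stem(word[:-3])
        if any(c in _VOWELS for c in stem):
            return stem
    if word.endswith("ied") and len(word) > 4:
        return word[:-3] + "y"
    if word.endswith("ed") and len(word) > 4:
        stem = _fix_stem(word[:-2])
        if any(c in _VOWELS for c in stem):
            # 'stated' -> 'stat' -> 'state'; plain stems stay as-is
            return stem if not stem.endswith("e") else stem
        return word
    if word.endswith("s"):
        return _strip_plural(word)
    return word
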