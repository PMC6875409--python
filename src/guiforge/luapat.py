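"""Pattern matching for the embedded scripting dialect.

Implements the dialect's pattern syntax (a distinct tradition from
POSIX/PCRE regular expressions): ``.`` matches any character, ``%d``
and friends are character classes with uppercase complements, sets
``[...]`` support ranges and negation, quantifiers are ``* + - ?``
(``-`` is the lazy star), ``^``/``$`` anchor at the string ends, and
``(...)`` captures.  Matching is leftmost with backtracking, positions
are 1-based and spans are inclusive, as scripts expect.

``%b``/``%f`` items and ``%1``-style back-references are not supported
and raise :class:`PatternError`.
"""

from __future__ import annotations

from typing import Optional

from .errors import PatternError

__all__ = ["find", "match_span", "PatternError"]

_POSITION_CAPTURE = -2
_OPEN_CAPTURE = -1

_PUNCT = set("!\"#$%&'()*+,-./:;<=>?@[\\]^_`{|}~")


def _class_match(ch: str, cl: str) -> bool:
    low = cl.lower()
    if low == "a":
        res = ch.isalpha() and ch.isascii()
    elif low == "c":
        res = ord(ch) < 32 or ord(ch) == 127
    elif low == "d":
        res = ch.isdigit() and ch.isascii()
    elif low == "l":
        res = ch.islower() and ch.isascii() and ch.isalpha()
    elif low == "p":
        res = ch in _PUNCT
    elif low == "s":
        res = ch in " \t\n\r\f\v"
    elif low == "u":
        res = ch.isupper() and ch.isascii() and ch.isalpha()
    elif low == "w":
        res = ch.isalnum() and ch.isascii()
    elif low == "x":
        res = ch in "0123456789abcdefABCDEF"
    else:
        return ch == cl  # escaped literal, e.g. %.
    if cl.isupper():
        return not res
    return res


class _Matcher:
    def __init__(self, s: str, p: str) -> None:
        self.s = s
        self.p = p
        self.caps: list[list[int]] = []  # [start, len]; len<0 == open/pos

    # ---- pattern item handling -------------------------------------
    def _class_end(self, pi: int) -> int:
        """Index just past the single pattern item starting at ``pi``."""
        p = self.p
        c = p[pi]
        pi += 1
        if c == "%":
            if pi >= len(p):
                raise PatternError("malformed pattern (ends with '%')")
            return pi + 1
        if c == "[":
            if pi < len(p) and p[pi] == "^":
                pi += 1
            first = True
            while True:
                if pi >= len(p):
                    raise PatternError("malformed pattern (missing ']')")
                c = p[pi]
                pi += 1
                if c == "%":
                    if pi >= len(p):
                        raise PatternError(
                            "malformed pattern (ends with '%')")
                    pi += 1
                elif c == "]" and not first:
                    return pi
                first = False
        return pi

    def _match_set(self, ch: str, pi: int, ep: int) -> bool:
        """Match ``ch`` against the set ``[pi+1 .. ep-2]``."""
        p = self.p
        negate = False
        pi += 1
        if p[pi] == "^":
            negate = True
            pi += 1
        res = False
        while pi < ep - 1:
            if p[pi] == "%":
                pi += 1
                if _class_match(ch, p[pi]):
                    res = True
                pi += 1
            elif pi + 2 < ep - 1 and p[pi + 1] == "-":
                if p[pi] <= ch <= p[pi + 2]:
                    res = True
                pi += 3
            else:
                if p[pi] == ch:
                    res = True
                pi += 1
        return res != negate

    def _single_match(self, si: int, pi: int, ep: int) -> bool:
        if si >= len(self.s):
            return False
        ch = self.s[si]
        c = self.p[pi]
        if c == ".":
            return True
        if c == "%":
            return _class_match(ch, self.p[pi + 1])
        if c == "[":
            return self._match_set(ch, pi, ep)
        return c == ch

    # ---- backtracking engine ---------------------------------------
    def _max_expand(self, si: int, pi: int, ep: int) -> Optional[int]:
        i = 0
        while self._single_match(si + i, pi, ep):
            i += 1
        while i >= 0:
            r = self._match(si + i, ep + 1)
            if r is not None:
                return r
            i -= 1
        return None

    def _min_expand(self, si: int, pi: int, ep: int) -> Optional[int]:
        while True:
            r = self._match(si, ep + 1)
            if r is not None:
                return r
            if self._single_match(si, pi, ep):
                si += 1
            else:
                return None

    def _start_capture(self, si: int, pi: int, what: int) -> Optional[int]:
        self.caps.append([si, what])
        r = self._match(si, pi)
        if r is None:
            self.caps.pop()
        return r

    def _end_capture(self, si: int, pi: int) -> Optional[int]:
        for cap in reversed(self.caps):
            if cap[1] == _OPEN_CAPTURE:
                cap[1] = si - cap[0]
                r = self._match(si, pi)
                if r is None:
                    cap[1] = _OPEN_CAPTURE
                return r
        raise PatternError("invalid pattern capture")

    def _match(self, si: int, pi: int) -> Optional[int]:
        p = self.p
        while True:
            if pi >= len(p):
                return si
            c = p[pi]
            if c == "(":
                if pi + 1 < len(p) and p[pi + 1] == ")":
                    return self._start_capture(si, pi + 2, _POSITION_CAPTURE)
                return self._start_capture(si, pi + 1, _OPEN_CAPTURE)
            if c == ")":
                return self._end_capture(si, pi + 1)
            if c == "$" and pi + 1 == len(p):
                return si if si == len(self.s) else None
            if c == "%" and pi + 1 < len(p):
                nxt = p[pi + 1]
                if nxt in "bf" or nxt.isdigit():
                    raise PatternError(
                        f"pattern item %{nxt} is not supported")
            ep = self._class_end(pi)
            quant = p[ep] if ep < len(p) else ""
            if quant == "?":
                if self._single_match(si, pi, ep):
                    r = self._match(si + 1, ep + 1)
                    if r is not None:
                        return r
                pi = ep + 1
                continue
            if quant == "+":
                if not self._single_match(si, pi, ep):
                    return None
                return self._max_expand(si + 1, pi, ep)
            if quant == "*":
                return self._max_expand(si, pi, ep)
            if quant == "-":
                return self._min_expand(si, pi, ep)
            if not self._single_match(si, pi, ep):
                return None
            si += 1
            pi = ep


def _check_pattern(pattern: str) -> None:
    """Full syntax scan so malformed patterns fail up front, not only
    when matching happens to reach the bad item."""
    checker = _Matcher("", pattern)
    pi = 1 if pattern.startswith("^") else 0
    depth = 0
    while pi < len(pattern):
        c = pattern[pi]
        if c == "(":
            depth += 1
            pi += 2 if pattern[pi + 1:pi + 2] == ")" else 1
            continue
        if c == ")":
            depth -= 1
            if depth < 0:
                raise PatternError("invalid pattern capture")
            pi += 1
            continue
        if c == "$" and pi + 1 == len(pattern):
            pi += 1
            continue
        if c == "%" and pi + 1 < len(pattern):
            nxt = pattern[pi + 1]
            if nxt in "bf" or nxt.isdigit():
                raise PatternError(f"pattern item %{nxt} is not supported")
        pi = checker._class_end(pi)
        if pi < len(pattern) and pattern[pi] in "*+-?":
            pi += 1
    if depth != 0:
        raise PatternError("unfinished capture")


def find(s: str, pattern: str, init: int = 1):
    """Leftmost match of ``pattern`` in ``s`` starting at 1-based ``init``.

    Returns ``(start, end, captures)`` with a 1-based inclusive span
    (``end == start - 1`` for an empty match) or ``None``.  Each capture
    is a string, or an integer position for ``()`` captures.
    """
    _check_pattern(pattern)
    if init < 0:
        init = max(len(s) + init + 1, 1)
    elif init == 0:
        init = 1
    si = init - 1
    if si > len(s):
        return None
    pi = 0
    anchored = pattern.startswith("^")
    if anchored:
        pi = 1
    while True:
        m = _Matcher(s, pattern)
        r = m._match(si, pi)
        if r is not None:
            captures = []
            for start, length in m.caps:
                if length == _POSITION_CAPTURE:
                    captures.append(start + 1)
                elif length == _OPEN_CAPTURE:
                    raise PatternError("unfinished capture")
                else:
                    captures.append(s[start:start + length])
            return (si + 1, r, captures)
        si += 1
        if anchored or si > len(s):
            return None


def match_span(s: str, pattern: str) -> Optional[tuple[int, int]]:
    """Span ``(start, end)`` of the leftmost match, 1-based inclusive,
    or ``None``.  Host-side entry point mirroring the dialect's own
    matching semantics."""
    r = find(s, pattern)
    if r is None:
        return None
    return (r[0], r[1])
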