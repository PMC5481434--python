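"""Boolean algebra over binary signal maps and marker-type quantification.

Expressions over scan names combine signal maps pixelwise: AND keeps pixels
present in both scans, OR pixels present in either, and NOT is complement
within the tissue mask.  The infix form ``A NOT B`` (pixels in the first
scan but not the second) is accepted and desugars to ``A AND (NOT B)``.
Precedence: NOT binds tighter than AND, AND tighter than OR.

From the CA19-9 and sTRA maps the five marker types are derived:
total CA19-9, total sTRA, CA19-9-only (``CA199 NOT STRA``), sTRA-only
(``STRA NOT CA199``) and dual (``CA199 AND STRA``), each as percent of
tissue pixels.  Per-core values are unweighted means over the core's tiles,
and a core expresses a marker when its averaged percent exceeds 1% (strict).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "Scan",
    "And",
    "Or",
    "Not",
    "MarkerQuant",
    "CoreQuant",
    "ExpressionError",
    "parse_expression",
    "evaluate_expression",
    "quantify_markers",
    "aggregate_core",
    "call_core_category",
    "PRESENCE_THRESHOLD",
    "CATEGORIES",
]

#: core-level presence threshold, percent of tissue pixels (strict >)
PRESENCE_THRESHOLD = 1.0

CATEGORIES = ("ca199_only_core", "stra_only_core", "both", "neither")


class ExpressionError(ValueError):
    """Malformed expression text or unknown scan name."""


@dataclass(frozen=True)
class Scan:
    name: str


@dataclass(frozen=True)
class And:
    left: object
    right: object


@dataclass(frozen=True)
class Or:
    left: object
    right: object


@dataclass(frozen=True)
class Not:
    operand: object


_TOKEN_RE = re.compile(r"\(|\)|[A-Za-z_][A-Za-z0-9_\-]*")
_KEYWORDS = {"AND", "OR", "NOT"}


def _tokenize(text: str) -> list[str]:
    tokens = []
    pos = 0
    for m in _TOKEN_RE.finditer(text):
        if text[pos : m.start()].strip():
            raise ExpressionError(f"unexpected characters at {pos}: {text[pos:m.start()]!r}")
        tok = m.group(0)
        tokens.append(tok.upper() if tok.upper() in _KEYWORDS else tok)
        pos = m.end()
    if text[pos:].strip():
        raise ExpressionError(f"unexpected characters at end: {text[pos:]!r}")
    return tokens


class _Parser:
    def __init__(self, tokens: list[str], known: set[str] | None):
        self.tokens = tokens
        self.i = 0
        self.known = known

    def peek(self) -> str | None:
        return self.tokens[self.i] if self.i < len(self.tokens) else None

    def next(self) -> str:
        tok = self.peek()
        if tok is None:
            raise ExpressionError("unexpected end of expression")
        self.i += 1
        return tok

    def parse(self):
        node = self.expr()
        if self.peek() is not None:
            raise ExpressionError(f"unexpected token {self.peek()!r}")
        return node

    def expr(self):
        node = self.term()
        while self.peek() == "OR":
            self.next()
            node = Or(node, self.term())
        return node

    def term(self):
        node = self.factor()
        while self.peek() in ("AND", "NOT"):
            op = self.next()
            rhs = self.factor()
            # infix NOT: "A NOT B" == A AND (NOT B)
            node = And(node, Not(rhs) if op == "NOT" else rhs)
        return node

    def factor(self):
        tok = self.next()
        if tok == "NOT":
            return Not(self.factor())
        if tok == "(":
            node = self.expr()
            if self.next() != ")":
                raise ExpressionError("missing closing parenthesis")
            return node
        if tok in (")", "AND", "OR"):
            raise ExpressionError(f"unexpected token {tok!r}")
        if self.known is not None and tok not in self.known:
            raise ExpressionError(f"unknown scan name {tok!r}")
        return Scan(tok)


def parse_expression(text: str, known_scans: Sequence[str] | None = None):
    """Parse expression text into an AST of Scan/And/Or/Not nodes."""

    tokens = _tokenize(text)
    if not tokens:
        raise ExpressionError("empty expression")
    return _Parser(tokens, set(known_scans) if known_scans is not None else None).parse()


def evaluate_expression(expr, maps: Mapping[str, np.ndarray], tissue: np.ndarray) -> np.ndarray:
    """Evaluate an expression AST to a boolean map, restricted to tissue.

    All referenced maps and the tissue mask must share one pixel grid.
    NOT complements within the tissue mask.
    """

    tissue = np.asarray(tissue, dtype=bool)
    for name, m in maps.items():
        if np.asarray(m).shape != tissue.shape:
            raise ValueError(f"map {name!r} does not match the tissue grid")

    def ev(node) -> np.ndarray:
        if isinstance(node, Scan):
            if node.name not in maps:
                raise ExpressionError(f"unknown scan name {node.name!r}")
            return np.asarray(maps[node.name], dtype=bool) & tissue
        if isinstance(node, And):
            return ev(node.left) & ev(node.right)
        if isinstance(node, Or):
            return ev(node.left) | ev(node.right)
        if isinstance(node, Not):
            return tissue & ~ev(node.operand)
        raise TypeError(f"not an expression node: {node!r}")

    return ev(expr)


@dataclass(frozen=True)
class MarkerQuant:
    """Per-tile marker percentages (percent of tissue pixels).

    Totals are computed as ``only + dual`` from the same pixel counts, so
    the conservation identities ``ca199_only + dual == ca199`` and
    ``stra_only + dual == stra`` hold bit-exactly.
    """

    ca199_only: float
    stra_only: float
    dual: float
    tissue_pixels: int
    counts: tuple[int, int, int] = field(default=(0, 0, 0), repr=False)  # only, only, dual

    @property
    def ca199(self) -> float:
        return self.ca199_only + self.dual

    @property
    def stra(self) -> float:
        return self.stra_only + self.dual

    def as_dict(self) -> dict[str, float]:
        return {
            "ca199": self.ca199,
            "stra": self.stra,
            "ca199_only": self.ca199_only,
            "stra_only": self.stra_only,
            "dual": self.dual,
        }


@dataclass(frozen=True)
class CoreQuant:
    """Core-level averages, presence calls and expression category."""

    core_id: str
    ca199: float
    stra: float
    ca199_only: float
    stra_only: float
    dual: float
    n_tiles: int
    ca199_present: bool
    stra_present: bool
    category: str

    def as_dict(self) -> dict:
        return {
            "core_id": self.core_id,
            "ca199": self.ca199,
            "stra": self.stra,
            "ca199_only": self.ca199_only,
            "stra_only": self.stra_only,
            "dual": self.dual,
            "n_tiles": self.n_tiles,
            "ca199_present": self.ca199_present,
            "stra_present": self.stra_present,
            "category": self.category,
        }


def quantify_markers(
    ca199_map: np.ndarray, stra_map: np.ndarray, tissue: np.ndarray
) -> MarkerQuant:
    """Derive the five marker-type percentages from the two glycan maps.

    Both maps must be contained in the tissue mask.  An empty tissue mask
    yields all-zero percentages.
    """

    ca = np.asarray(ca199_map, dtype=bool)
    st = np.asarray(stra_map, dtype=bool)
    tissue = np.asarray(tissue, dtype=bool)
    if ca.shape != tissue.shape or st.shape != tissue.shape:
        raise ValueError("maps and tissue mask must share one grid")
    if np.any(ca & ~tissue) or np.any(st & ~tissue):
        raise ValueError("signal maps must be contained in the tissue mask")

    n_tissue = int(tissue.sum())
    n_dual = int((ca & st).sum())
    n_ca_only = int((ca & ~st).sum())
    n_st_only = int((st & ~ca).sum())
    if n_tissue == 0:
        pct = (0.0, 0.0, 0.0)
    else:
        pct = (
            100.0 * n_ca_only / n_tissue,
            100.0 * n_st_only / n_tissue,
            100.0 * n_dual / n_tissue,
        )
    return MarkerQuant(
        ca199_only=pct[0],
        stra_only=pct[1],
        dual=pct[2],
        tissue_pixels=n_tissue,
        counts=(n_ca_only, n_st_only, n_dual),
    )


def aggregate_core(
    core_id: str,
    tiles: Sequence[MarkerQuant],
    presence_threshold: float = PRESENCE_THRESHOLD,
    weight_by_tissue: bool = False,
) -> CoreQuant:
    """Average per-tile percentages into a core-level quantification.

    The default is the unweighted mean over tiles; ``weight_by_tissue``
    switches to a tissue-pixel-weighted mean (sensitivity analysis only).
    Tiles with zero tissue pixels carry no percent-of-tissue information and
    are excluded from the average.
    """

    tiles = [t for t in tiles if t.tissue_pixels > 0]
    if not tiles:
        raise ValueError("no tiles with tissue to aggregate")
    if weight_by_tissue:
        w = np.array([t.tissue_pixels for t in tiles], dtype=float)
        w /= w.sum()
    else:
        w = np.full(len(tiles), 1.0 / len(tiles))

    def mean(attr: str) -> float:
        return float(np.dot(w, [getattr(t, attr) for t in tiles]))

    ca199_only, stra_only, dual = mean("ca199_only"), mean("stra_only"), mean("dual")
    ca199, stra = ca199_only + dual, stra_only + dual
    ca_p, st_p = ca199 > presence_threshold, stra > presence_threshold
    return CoreQuant(
        core_id=core_id,
        ca199=ca199,
        stra=stra,
        ca199_only=ca199_only,
        stra_only=stra_only,
        dual=dual,
        n_tiles=len(tiles),
        ca199_present=ca_p,
        stra_present=st_p,
        category=_category(ca_p, st_p),
    )


def _category(ca199_present: bool, stra_present: bool) -> str:
    if ca199_present and stra_present:
        return "both"
    if ca199_present:
        return "ca199_only_core"
    if stra_present:
        return "stra_only_core"
    return "neither"


def call_core_category(
    ca199: float, stra: float, presence_threshold: float = PRESENCE_THRESHOLD
) -> str:
    """Expression category of a core from its averaged total-glycan percents.

    A marker counts as expressed when its averaged percent is strictly
    greater than the threshold (default 1% of tissue pixels).
    """

    return _category(ca199 > presence_threshold, stra > presence_threshold)
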