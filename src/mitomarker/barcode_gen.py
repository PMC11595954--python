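"""Four-color DNA barcode images and QR payload text.

Each base becomes one solid vertical bar, left to right in sequence
order: A green, T red, G black, C blue. Encoding and decoding are exact
inverses for every geometry, so a rendered barcode is a lossless carrier
of the marker sequence. The QR payload is a single stable FASTA entry
(``>accession|organism|gene`` + sequence); rendering that payload with any
standard QR encoder reproduces the scannable code.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from PIL import Image

from mitomarker.errors import BarcodeError
from mitomarker.mito_io import GeneFeature

RGB = tuple[int, int, int]


@dataclass(frozen=True)
class BarcodePalette:
    """Bijective base -> color map over {A, T, G, C}."""

    colors: tuple[tuple[str, RGB], ...] = (
        ("A", (0, 128, 0)),   # green
        ("T", (255, 0, 0)),   # red
        ("G", (0, 0, 0)),     # black
        ("C", (0, 0, 255)),   # blue
    )

    def __post_init__(self):
        bases = [b for b, _ in self.colors]
        rgbs = [c for _, c in self.colors]
        if sorted(bases) != ["A", "C", "G", "T"]:
            raise BarcodeError("palette must cover exactly {A, T, G, C}")
        if len(set(rgbs)) != 4:
            raise BarcodeError("palette colors must be distinct")

    def color(self, base: str) -> RGB:
        for b, c in self.colors:
            if b == base:
                return c
        raise BarcodeError(f"base {base!r} not in palette")

    def base(self, rgb: RGB) -> str:
        for b, c in self.colors:
            if c == tuple(rgb):
                return b
        raise BarcodeError(f"color {rgb} not in palette")


DEFAULT_PALETTE = BarcodePalette()


@dataclass(frozen=True)
class BarcodeGeometry:
    bar_width_px: int = 3
    bar_height_px: int = 60

    def __post_init__(self):
        if self.bar_width_px < 1 or self.bar_height_px < 1:
            raise BarcodeError("bar dimensions must be >= 1 px")


def _check_sequence(sequence: str) -> str:
    seq = sequence.upper()
    if not seq:
        raise BarcodeError("cannot encode an empty sequence")
    bad = set(seq) - set("ATGC")
    if bad:
        raise BarcodeError(
            f"barcodes encode resolved sequences only; illegal characters {sorted(bad)}"
        )
    return seq


def encode_barcode(
    sequence: str,
    palette: BarcodePalette = DEFAULT_PALETTE,
    geometry: BarcodeGeometry = BarcodeGeometry(),
) -> Image.Image:
    """Render a sequence as a four-color bar image (one bar per base)."""
    seq = _check_sequence(sequence)
    w, h = geometry.bar_width_px, geometry.bar_height_px
    img = Image.new("RGB", (len(seq) * w, h))
    px = img.load()
    for i, base in enumerate(seq):
        color = palette.color(base)
        for x in range(i * w, (i + 1) * w):
            for y in range(h):
                px[x, y] = color
    return img


def decode_barcode(
    image: Image.Image,
    palette: BarcodePalette = DEFAULT_PALETTE,
    bar_width_px: int | None = None,
) -> str:
    """Invert encode_barcode; any off-palette pixel column is an error."""
    img = image.convert("RGB")
    width, height = img.size
    px = img.load()
    if bar_width_px is None:
        # infer bar width: gcd of the horizontal color-run lengths and the
        # image width (exact whenever adjacent bases differ somewhere)
        import math

        g = width
        run = 1
        for x in range(1, width):
            if px[x, 0] == px[x - 1, 0]:
                run += 1
            else:
                g = math.gcd(g, run)
                run = 1
        bar_width_px = math.gcd(g, run)
    if width % bar_width_px != 0:
        raise BarcodeError(f"image width {width} not a multiple of bar width {bar_width_px}")
    bases = []
    for i in range(width // bar_width_px):
        x0 = i * bar_width_px
        color = px[x0, 0]
        for x in range(x0, x0 + bar_width_px):
            for y in range(height):
                if px[x, y] != color:
                    raise BarcodeError(f"bar {i} is not a solid color (column {x})")
        try:
            bases.append(palette.base(color))
        except BarcodeError as exc:
            raise BarcodeError(f"off-palette color at column {x0}: {exc}") from exc
    return "".join(bases)


def barcode_svg(
    sequence: str,
    palette: BarcodePalette = DEFAULT_PALETTE,
    geometry: BarcodeGeometry = BarcodeGeometry(),
) -> str:
    """Resolution-independent SVG rendering (the canonical artifact)."""
    seq = _check_sequence(sequence)
    w, h = geometry.bar_width_px, geometry.bar_height_px
    total = len(seq) * w
    parts = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{total}" height="{h}" '
        f'viewBox="0 0 {total} {h}">'
    ]
    for i, base in enumerate(seq):
        r, g, b = palette.color(base)
        parts.append(
            f'<rect x="{i * w}" y="0" width="{w}" height="{h}" '
            f'fill="rgb({r},{g},{b})"/>'
        )
    parts.append("</svg>")
    return "\n".join(parts)


def make_qr_payload(
    feature: GeneFeature, accession: str, organism: str
) -> str:
    """Stable FASTA payload identifying a barcode marker sequence.

    The text is what a QR encoder would render; it parses back with any
    FASTA reader, so scanning recovers accession, organism, gene and the
    full marker sequence.
    """
    for name, value in (("accession", accession), ("organism", organism),
                        ("gene", feature.gene_name), ("sequence", feature.sequence)):
        if not value:
            raise BarcodeError(f"missing provenance field: {name}")
    return f">{accession}|{organism}|{feature.gene_name}\n{feature.sequence}\n"


def write_barcode(
    sequence: str,
    path: str | Path,
    palette: BarcodePalette = DEFAULT_PALETTE,
    geometry: BarcodeGeometry = BarcodeGeometry(),
) -> Path:
    """Write PNG or SVG depending on the file suffix."""
    path = Path(path)
    if path.suffix.lower() == ".svg":
        path.write_text(barcode_svg(sequence, palette, geometry))
    else:
        encode_barcode(sequence, palette, geometry).save(path)
    return path
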