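import numpy as np
import pytest

from space_stomata import CotyledonMap, Outline, synth_cotyledon, synth_sector


@pytest.fixture
def unit_square() -> Outline:
    return Outline(np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]]))


@pytest.fixture
def square_100() -> Outline:
    return Outline(np.array([[0.0, 0.0], [100.0, 0.0], [100.0, 100.0], [0.0, 100.0]]))


@pytest.fixture(scope="session")
def cotyledon() -> Outline:
    """A realistic-scale synthetic cotyledon blade (~2000 x 1200 µm)."""
    return synth_cotyledon(seed=42)


@pytest.fixture(scope="session")
def sector(cotyledon) -> Outline:
    """A mid-window sector (~20,000 µm²) inside the session cotyledon."""
    return synth_sector(20_000, cotyledon, seed=43)


@pytest.fixture
def square_map() -> CotyledonMap:
    """A 1000x1000 µm square cotyledon with a centred 100x100 sector and a few stomata."""
    cot = Outline(np.array([[0.0, 0.0], [1000.0, 0.0], [1000.0, 1000.0], [0.0, 1000.0]]))
    sec = Outline(np.array([[450.0, 450.0], [550.0, 450.0], [550.0, 550.0], [450.0, 550.0]]))
    stomata = np.array(
        [
            [500.0, 500.0],  # inside sector
            [500.0, 600.0],  # 50 µm beyond sector boundary
            [500.0, 700.0],  # 150 µm out
            [100.0, 100.0],  # far
            [900.0, 900.0],  # far
        ]
    )
    return CotyledonMap(cotyledon=cot, sectors=[sec], stomata=stomata, label="fixture")


def segment_distance_oracle(p: np.ndarray, vertices: np.ndarray) -> float:
    """Brute-force minimum point-to-segment distance over a closed ring."""
    best = np.inf
    n = len(vertices)
    for i in range(n):
        a = vertices[i]
        b = vertices[(i + 1) % n]
        ab = b - a
        t = np.clip(np.dot(p - a, ab) / np.dot(ab, ab), 0.0, 1.0)
        best = min(best, float(np.linalg.norm(p - (a + t * ab))))
    return best


def ray_cast_oracle(p: np.ndarray, vertices: np.ndarray) -> bool:
    """Independent even-odd ray-casting point-in-polygon test (open ray along +x)."""
    x, y = p
    n = len(vertices)
    inside = False
    for i in range(n):
        x1, y1 = vertices[i]
        x2, y2 = vertices[(i + 1) % n]
        if (y1 > y) != (y2 > y):
            x_cross = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
            if x < x_cross:
                inside = not inside
    return inside
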