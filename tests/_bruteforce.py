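"""Independent brute-force Agatston enumerator used as a test oracle.

Pure-python BFS over voxel sets — no scipy, no shared code with the
implementation under test.
"""

from collections import Counter

N26 = [(dz, dy, dx) for dz in (-1, 0, 1) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
       if (dz, dy, dx) != (0, 0, 0)]
N8 = [(dy, dx) for dy in (-1, 0, 1) for dx in (-1, 0, 1) if (dy, dx) != (0, 0)]


def _components(coords, neighbours):
    remaining = set(coords)
    comps = []
    while remaining:
        seed = remaining.pop()
        comp = {seed}
        stack = [seed]
        while stack:
            cur = stack.pop()
            for off in neighbours:
                nb = tuple(c + o for c, o in zip(cur, off))
                if nb in remaining:
                    remaining.remove(nb)
                    comp.add(nb)
                    stack.append(nb)
        comps.append(comp)
    return comps


def _cofactor(peak):
    if peak < 200:
        return 1
    if peak < 300:
        return 2
    if peak < 400:
        return 3
    return 4


def brute_force_report(hu, spacing, labels):
    """Total/per-vessel/excluded Agatston scores by exhaustive enumeration.

    hu, labels: 3D arrays; spacing: (dz, dy, dx) in mm.
    """
    dz, dy, dx = spacing
    pixel_area = dy * dx
    thickness = dz / 3.0
    coords = [tuple(c) for c in zip(*((hu >= 130).nonzero()))]
    per_vessel = {1: 0.0, 2: 0.0, 3: 0.0, 4: 0.0}
    excluded = 0.0
    for comp in _components(coords, N26):
        score = 0.0
        for z in sorted({c[0] for c in comp}):
            plane = [(c[1], c[2]) for c in comp if c[0] == z]
            for comp2d in _components(plane, N8):
                area = len(comp2d) * pixel_area
                if area < 1.0:
                    continue
                peak = max(float(hu[z, y, x]) for (y, x) in comp2d)
                score += area * _cofactor(peak) * thickness
        if score == 0.0:
            continue
        votes = Counter(int(labels[c]) for c in comp)
        best = max([1, 2, 3, 4, 5, 0],
                   key=lambda k: (votes.get(k, 0), -[1, 2, 3, 4, 5, 0].index(k)))
        if best in per_vessel:
            per_vessel[best] += score
        else:
            excluded += score
    total = sum(per_vessel.values())
    if total < 1:
        cat = 0
    elif total <= 10:
        cat = 1
    elif total <= 100:
        cat = 2
    elif total <= 400:
        cat = 3
    else:
        cat = 4
    return {"per_vessel": per_vessel, "total": total, "excluded": excluded, "category": cat}
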