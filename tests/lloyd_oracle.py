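"""Brute-force Lloyd clustering, written with plain loops as an independent
oracle for the vectorised k-means implementation. Mirrors the contract:
exact Euclidean nearest center (lowest index on ties), all centers updated
to assigned-point means, empty clusters re-seeded to the point farthest
from its nearest center, stop when assignments repeat."""

import math


def lloyd_bruteforce(points, init_centers, max_iter=300):
    centers = [list(c) for c in init_centers]
    k = len(centers)
    assign = [-1] * len(points)
    for _ in range(max_iter):
        def dist2(p, c):
            return sum((pi - ci) ** 2 for pi, ci in zip(p, c))

        def assign_all():
            out = []
            for p in points:
                best, bestd = 0, math.inf
                for j, c in enumerate(centers):
                    d = dist2(p, c)
                    if d < bestd:
                        best, bestd = j, d
                out.append(best)
            return out

        new_assign = assign_all()
        for j in range(k):
            if j not in new_assign:
                far_i, far_d = 0, -1.0
                for i, p in enumerate(points):
                    d = min(dist2(p, c) for c in centers)
                    if d > far_d:
                        far_i, far_d = i, d
                centers[j] = list(points[far_i])
                new_assign = assign_all()
        if new_assign == assign:
            break
        assign = new_assign
        for j in range(k):
            members = [points[i] for i, a in enumerate(assign) if a == j]
            if members:
                centers[j] = [sum(col) / len(members) for col in zip(*members)]
    sse = sum(
        sum((pi - ci) ** 2 for pi, ci in zip(p, centers[a]))
        for p, a in zip(points, assign)
    )
    return assign, centers, sse
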