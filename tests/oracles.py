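"""Independent straight-line reimplementations used as test oracles.

Everything here is deliberately loop-based and dependency-free: explicit
iteration over nodes, edges and signature/node pairs, no vectorisation, no
reuse of the package's numerical code beyond reading parameter arrays.
"""

import math

import numpy as np


def gelu_scalar(x: float) -> float:
    c = math.sqrt(2.0 / math.pi)
    return 0.5 * x * (1.0 + math.tanh(c * (x + 0.044715 * x ** 3)))


def elu_scalar(x: float) -> float:
    return x if x > 0 else math.exp(x) - 1.0


def leaky_scalar(x: float, slope: float) -> float:
    return x if x > 0 else slope * x


def oracle_layernorm(x: np.ndarray, gamma: np.ndarray, beta: np.ndarray,
                     eps: float = 1e-5) -> np.ndarray:
    out = np.zeros_like(x, dtype=float)
    for i in range(x.shape[0]):
        row = x[i]
        mu = sum(row) / len(row)
        var = sum((v - mu) ** 2 for v in row) / len(row)
        for j in range(x.shape[1]):
            out[i, j] = (row[j] - mu) / math.sqrt(var + eps) * gamma[j] + beta[j]
    return out


def oracle_mlp(x: np.ndarray, w1, b1, w2, b2) -> np.ndarray:
    n, d = x.shape
    hidden_dim = w1.shape[1]
    out = np.zeros((n, w2.shape[1]))
    for i in range(n):
        h = [gelu_scalar(sum(x[i, k] * w1[k, j] for k in range(d)) + b1[j])
             for j in range(hidden_dim)]
        for j in range(w2.shape[1]):
            out[i, j] = sum(h[k] * w2[k, j] for k in range(hidden_dim)) + b2[j]
    return out


def oracle_gat(h: np.ndarray, adj: np.ndarray, w: np.ndarray, a: np.ndarray,
               slope: float):
    """Per-edge score, per-node softmax (self-loop included), aggregate, ELU."""
    n, d = h.shape
    hw = np.array([[sum(h[i, k] * w[k, j] for k in range(d)) for j in range(d)]
                   for i in range(n)])
    a = a.reshape(-1)
    alpha = np.zeros((n, n))
    out = np.zeros((n, d))
    for i in range(n):
        neigh = [j for j in range(n) if adj[i, j] or j == i]
        scores = []
        for j in neigh:
            e = sum(a[k] * hw[i, k] for k in range(d)) \
                + sum(a[d + k] * hw[j, k] for k in range(d))
            scores.append(leaky_scalar(e, slope))
        m = max(scores)
        exps = [math.exp(s - m) for s in scores]
        total = sum(exps)
        for j, ex in zip(neigh, exps):
            alpha[i, j] = ex / total
        for k in range(d):
            out[i, k] = elu_scalar(sum(alpha[i, j] * hw[j, k] for j in neigh))
    return out, alpha


def oracle_gam(b: np.ndarray, h: np.ndarray, wq, wk, wv, scale: float):
    """Explicit loop over (signature, node) pairs."""
    m, d = b.shape
    n = h.shape[0]
    q = b @ wq
    k = h @ wk
    v = h @ wv
    attn = np.zeros((m, n))
    fused = np.zeros((m, d))
    for mi in range(m):
        scores = [sum(q[mi, c] * k[ni, c] for c in range(d)) / scale
                  for ni in range(n)]
        mx = max(scores)
        exps = [math.exp(s - mx) for s in scores]
        total = sum(exps)
        for ni in range(n):
            attn[mi, ni] = exps[ni] / total
        for c in range(d):
            fused[mi, c] = sum(attn[mi, ni] * v[ni, c] for ni in range(n))
    return fused, attn


def oracle_pool(x: np.ndarray, v, u, w):
    """tanh/sigmoid gate, elementwise product, softmax, weighted sum."""
    kk, d = x.shape
    width = v.shape[1]
    scores = []
    for i in range(kk):
        gv = [math.tanh(sum(x[i, c] * v[c, j] for c in range(d)))
              for j in range(width)]
        gu = [1.0 / (1.0 + math.exp(-sum(x[i, c] * u[c, j] for c in range(d))))
              for j in range(width)]
        scores.append(sum(w[j, 0] * gv[j] * gu[j] for j in range(width)))
    mx = max(scores)
    exps = [math.exp(s - mx) for s in scores]
    total = sum(exps)
    weights = np.array([e / total for e in exps])
    pooled = np.array([sum(weights[i] * x[i, c] for i in range(kk))
                       for c in range(d)])
    return pooled, weights


def oracle_mixer(h: np.ndarray, adj: np.ndarray, layer) -> np.ndarray:
    """One GraphMixer layer recomputed from the layer's parameter arrays."""
    nml = layer.nml
    ga, _ = oracle_gat(h, adj, nml.gat.W.data, nml.gat.a.data, nml.gat.slope)
    ln1 = oracle_layernorm(ga, nml.norm.gamma.data, nml.norm.beta.data)
    mixed = oracle_mlp(ln1, nml.mlp.fc1.weight.data, nml.mlp.fc1.bias.data,
                       nml.mlp.fc2.weight.data, nml.mlp.fc2.bias.data)
    h1 = h + mixed
    cml = layer.cml
    ln2 = oracle_layernorm(h1, cml.norm.gamma.data, cml.norm.beta.data)
    return h1 + oracle_mlp(ln2, cml.mlp.fc1.weight.data, cml.mlp.fc1.bias.data,
                           cml.mlp.fc2.weight.data, cml.mlp.fc2.bias.data)


def oracle_cindex(risks, times, events) -> float:
    num = den = 0.0
    n = len(times)
    for i in range(n):
        if events[i] != 1:
            continue
        for j in range(n):
            if times[i] < times[j]:
                den += 1
                if risks[i] > risks[j]:
                    num += 1
                elif risks[i] == risks[j]:
                    num += 0.5
    if den == 0:
        raise ZeroDivisionError("no comparable pairs")
    return num / den


def oracle_ntxent(z: np.ndarray, tau: float) -> float:
    """Brute-force NT-Xent: normalize, full similarity table, per-anchor sum."""
    z = np.array([row / math.sqrt(sum(v * v for v in row)) for row in z])
    n2 = len(z)
    total = 0.0
    for i in range(n2):
        pos = i ^ 1
        sims = {j: sum(z[i, c] * z[j, c] for c in range(z.shape[1])) / tau
                for j in range(n2) if j != i}
        denom = sum(math.exp(s) for s in sims.values())
        total += -math.log(math.exp(sims[pos]) / denom)
    return total / n2
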