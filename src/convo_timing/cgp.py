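"""Cartesian genetic programming classifier over speech-timing features.

A genotype is a fixed-length integer chromosome encoding a feed-forward
arithmetic graph: fifty nodes, each with a function gene over {+, −, ×,
protected ÷} and two connection genes addressing any input or any earlier
node (acyclic by construction), plus one output gene per class output.
Evolution is a (1+λ) strategy: the fittest chromosome (training accuracy)
survives each generation, offspring are its per-gene mutants, and ties
between parent and offspring go to the offspring so neutral drift can
traverse fitness plateaus.  The validation subset never touches the
fitness; it selects which genotype from the whole run is reported.

Because only nodes reachable from the outputs are evaluated, most of the
chromosome is silent at any time — mutations there are neutral and keep
the search moving.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

_FUNCTION_NAMES = ("add", "sub", "mul", "div")
_N_FUNCTIONS = 4
_DIV_EPS = 1e-9


@dataclass
class CgpConfig:
    n_inputs: int = 10
    n_nodes: int = 50
    n_outputs: int = 1
    mutation_rate: float = 0.1
    max_iterations: int = 15000
    lam: int = 4                      # offspring per generation (1+lambda)
    mutation_mode: str = "per_gene"   # or "fixed_fraction": exactly 10% of genes
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_nodes <= 0 or self.n_inputs <= 0 or self.n_outputs <= 0:
            raise ValueError("n_inputs, n_nodes, n_outputs must be positive")
        if not 0 < self.mutation_rate <= 1:
            raise ValueError("mutation_rate must be in (0, 1]")
        if self.max_iterations < 0 or self.lam < 1:
            raise ValueError("max_iterations must be >= 0 and lam >= 1")

    @property
    def n_genes(self) -> int:
        return 3 * self.n_nodes + self.n_outputs

    def gene_ranges(self) -> np.ndarray:
        """Exclusive upper bound of each gene's legal value range."""
        hi = np.empty(self.n_genes, dtype=np.int64)
        for i in range(self.n_nodes):
            hi[3 * i] = _N_FUNCTIONS
            hi[3 * i + 1] = hi[3 * i + 2] = self.n_inputs + i
        hi[3 * self.n_nodes:] = self.n_inputs + self.n_nodes
        return hi


@dataclass
class CgpGenotype:
    """Integer chromosome; genes laid out node-wise then outputs."""

    genes: np.ndarray
    config: CgpConfig

    def __post_init__(self) -> None:
        self.genes = np.asarray(self.genes, dtype=np.int64)
        hi = self.config.gene_ranges()
        if self.genes.shape != hi.shape:
            raise ValueError(f"expected {hi.size} genes, got {self.genes.size}")
        if np.any(self.genes < 0) or np.any(self.genes >= hi):
            bad = int(np.flatnonzero((self.genes < 0) | (self.genes >= hi))[0])
            raise ValueError(f"gene {bad} out of range: {self.genes[bad]} (max {hi[bad] - 1})")

    def active_nodes(self) -> list[int]:
        """Node indices reachable from the outputs, ascending."""
        cfg = self.config
        needed: set[int] = set()
        stack = [int(g) for g in self.genes[3 * cfg.n_nodes:]]
        while stack:
            ref = stack.pop()
            node = ref - cfg.n_inputs
            if node >= 0 and node not in needed:
                needed.add(node)
                stack.append(int(self.genes[3 * node + 1]))
                stack.append(int(self.genes[3 * node + 2]))
        return sorted(needed)

    def active_inputs(self) -> list[int]:
        """Input indices feeding the active subgraph."""
        cfg = self.config
        used: set[int] = set()
        for ref in self.genes[3 * cfg.n_nodes:]:
            if ref < cfg.n_inputs:
                used.add(int(ref))
        for node in self.active_nodes():
            for ref in (self.genes[3 * node + 1], self.genes[3 * node + 2]):
                if ref < cfg.n_inputs:
                    used.add(int(ref))
        return sorted(used)


def random_genotype(config: CgpConfig, rng: np.random.Generator) -> CgpGenotype:
    hi = config.gene_ranges()
    return CgpGenotype(rng.integers(0, hi), config)


def _apply(func: int, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    if func == 0:
        return a + b
    if func == 1:
        return a - b
    if func == 2:
        return a * b
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        out = np.where(np.abs(b) < _DIV_EPS, 1.0, a / b)
    return out


def decode_eval(genotype: CgpGenotype, inputs: np.ndarray) -> np.ndarray:
    """Evaluate the encoded graph.

    ``inputs`` is either one feature vector (n_inputs,) or a matrix
    (n_samples, n_inputs); only active nodes are evaluated, in index
    order.  Returns (n_outputs,) or (n_samples, n_outputs).
    """
    cfg = genotype.config
    x = np.asarray(inputs, dtype=float)
    single = x.ndim == 1
    if single:
        x = x[None, :]
    if x.shape[1] != cfg.n_inputs:
        raise ValueError(f"expected {cfg.n_inputs} inputs, got {x.shape[1]}")
    values: dict[int, np.ndarray] = {i: x[:, i] for i in range(cfg.n_inputs)}
    with np.errstate(all="ignore"):
        for node in genotype.active_nodes():
            f, c1, c2 = genotype.genes[3 * node: 3 * node + 3]
            values[cfg.n_inputs + node] = _apply(int(f), values[int(c1)], values[int(c2)])
    out = np.stack(
        [values[int(g)] for g in genotype.genes[3 * cfg.n_nodes:]], axis=1
    )
    return out[0] if single else out


def classify(outputs: np.ndarray, n_classes: int) -> np.ndarray:
    """Output values -> class labels.

    Non-finite outputs are clamped to 0 first (protected division does not
    remove overflow).  Binary (one output): class 1 iff the output is
    >= 0.  Multi-class: argmax over per-class outputs, ties to the lowest
    index.
    """
    o = np.asarray(outputs, dtype=float)
    single = o.ndim == 1
    if single:
        o = o[None, :]
    o = np.where(np.isfinite(o), o, 0.0)
    if o.shape[1] == 1:
        labels = (o[:, 0] >= 0).astype(int)
    else:
        if o.shape[1] != n_classes:
            raise ValueError(f"expected {n_classes} outputs, got {o.shape[1]}")
        labels = np.argmax(o, axis=1)
    return labels[0] if single else labels


def mutate(genotype: CgpGenotype, mutation_rate: float, rng: np.random.Generator,
           mode: str = "per_gene") -> CgpGenotype:
    """Point mutation: resample genes uniformly within their legal ranges.

    "per_gene": each gene mutates independently with probability
    ``mutation_rate``; "fixed_fraction": exactly
    round(rate x n_genes) genes, chosen without replacement.  The
    feed-forward invariant holds by construction of the ranges.
    """
    hi = genotype.config.gene_ranges()
    genes = genotype.genes.copy()
    if mode == "per_gene":
        mask = rng.random(genes.size) < mutation_rate
        idx = np.flatnonzero(mask)
    elif mode == "fixed_fraction":
        k = int(round(mutation_rate * genes.size))
        idx = rng.choice(genes.size, size=k, replace=False)
    else:
        raise ValueError(f"unknown mutation mode {mode!r}")
    if idx.size:
        genes[idx] = rng.integers(0, hi[idx])
    return CgpGenotype(genes, genotype.config)


def _accuracy(genotype: CgpGenotype, X: np.ndarray, y: np.ndarray, n_classes: int) -> float:
    labels = classify(decode_eval(genotype, X), n_classes)
    return float(np.mean(labels == y))


@dataclass
class EvolveResult:
    best: CgpGenotype              # best validation accuracy seen
    best_val_accuracy: float
    final_parent: CgpGenotype      # fittest on training at the last generation
    train_trace: list[float]       # best training fitness per generation


def evolve(
    train: tuple[np.ndarray, np.ndarray],
    validation: tuple[np.ndarray, np.ndarray] | None,
    config: CgpConfig,
    rng: np.random.Generator | int | None = None,
) -> EvolveResult:
    """(1+λ) evolution of a classifier; fitness is training accuracy.

    Ties between the parent and an equally fit offspring are resolved in
    favour of the offspring (neutral drift).  The validation set plays the
    model-selection role only: the genotype with the best validation
    accuracy over the whole run is returned as ``best``.
    """
    if rng is None or isinstance(rng, int):
        rng = np.random.default_rng(config.seed if rng is None else rng)
    X, y = np.asarray(train[0], float), np.asarray(train[1])
    if X.size == 0:
        raise ValueError("empty training set")
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("training set contains a single class")
    n_classes = int(classes.size)
    if not np.all(np.isfinite(X)):
        raise ValueError("training features must be finite")

    def active_gene_mask(genotype: CgpGenotype) -> np.ndarray:
        mask = np.zeros(config.n_genes, dtype=bool)
        for node in genotype.active_nodes():
            mask[3 * node: 3 * node + 3] = True
        mask[3 * config.n_nodes:] = True
        return mask

    parent = random_genotype(config, rng)
    parent_fit = _accuracy(parent, X, y, n_classes)
    parent_mask = active_gene_mask(parent)
    if validation is not None:
        Xv, yv = np.asarray(validation[0], float), np.asarray(validation[1])
        best, best_val = parent, _accuracy(parent, Xv, yv, n_classes)
    else:
        best, best_val = parent, parent_fit
    best_train = parent_fit
    trace = [parent_fit]

    for _ in range(config.max_iterations):
        changed = False
        for _ in range(config.lam):
            child = mutate(parent, config.mutation_rate, rng, config.mutation_mode)
            touched = child.genes != parent.genes
            if not (touched & parent_mask).any():
                # mutations hit silent genes only: the active graph and hence
                # the fitness are unchanged — adopt the child without
                # re-evaluating (neutral drift, same tie rule as below)
                parent = child
                continue
            fit = _accuracy(child, X, y, n_classes)
            if fit >= parent_fit:       # offspring wins ties: neutral drift
                parent, parent_fit = child, fit
                parent_mask = active_gene_mask(child)
                changed = True
        trace.append(parent_fit)
        if changed and validation is not None:
            val = _accuracy(parent, Xv, yv, n_classes)
            # ties on the (small) validation set go to the genotype with the
            # better training fitness, i.e. the more evolved one
            if val > best_val or (val == best_val and parent_fit >= best_train):
                best, best_val, best_train = parent, val, parent_fit
        elif changed and validation is None and parent_fit >= best_val:
            best, best_val = parent, parent_fit
    return EvolveResult(best=best, best_val_accuracy=best_val,
                        final_parent=parent, train_trace=trace)


def stratified_folds(y: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Fold index per sample; class proportions balanced across folds."""
    y = np.asarray(y)
    folds = np.empty(y.shape[0], dtype=int)
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        if idx.size < k:
            raise ValueError(f"class {cls!r} has {idx.size} samples, fewer than k={k}")
        idx = rng.permutation(idx)
        folds[idx] = np.arange(idx.size) % k
    return folds


def stratified_split(
    y: np.ndarray, rng: np.random.Generator,
    proportions: tuple[float, float, float] = (0.6, 0.2, 0.2),
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Disjoint stratified train/validation/test index sets (60/20/20)."""
    if not math.isclose(sum(proportions), 1.0):
        raise ValueError("proportions must sum to 1")
    y = np.asarray(y)
    parts: list[list[int]] = [[], [], []]
    for cls in np.unique(y):
        idx = rng.permutation(np.flatnonzero(y == cls))
        n = idx.size
        n_tr = int(round(proportions[0] * n))
        n_va = int(round(proportions[1] * n))
        parts[0].extend(idx[:n_tr])
        parts[1].extend(idx[n_tr:n_tr + n_va])
        parts[2].extend(idx[n_tr + n_va:])
    return tuple(np.sort(np.array(p, dtype=int)) for p in parts)  # type: ignore[return-value]


@dataclass
class CrossValResult:
    fold_accuracies: np.ndarray    # (runs, k) test accuracy per fold
    run_means: np.ndarray          # (runs,)
    mean_accuracy: float           # mean over run means
    sd_accuracy: float             # SD over run means
    pooled_mean: float             # mean over all fold accuracies
    winners: list = field(default_factory=list)  # best genotype per run


def crossvalidate(
    X: np.ndarray,
    y: np.ndarray,
    config: CgpConfig,
    k: int = 5,
    runs: int = 10,
    seed: int | None = None,
    scale_inputs: bool = False,
) -> CrossValResult:
    """Repeated stratified k-fold cross-validation of the evolved classifier.

    Per fold rotation: one fold tests, the next validates, the remaining
    three train.  Fold assignments are resampled for each of the ``runs``
    independently seeded repetitions; accuracy is reported both as the
    mean over per-run means and pooled over all folds.

    ``scale_inputs`` min-max scales features into [0, 1] using the training
    folds' ranges (arithmetic graphs behave much better on bounded inputs);
    the scaling never sees validation or test samples.
    """
    X = np.asarray(X, float)
    y_arr = np.asarray(y)
    classes, y_enc = np.unique(y_arr, return_inverse=True)
    if classes.size < 2:
        raise ValueError("need at least two classes")
    master = np.random.default_rng(config.seed if seed is None else seed)
    fold_acc = np.empty((runs, k))
    winners = []
    for r in range(runs):
        rng = np.random.default_rng(master.integers(0, 2**31 - 1))
        folds = stratified_folds(y_enc, k, rng)
        run_best = None
        for f in range(k):
            test = folds == f
            val = folds == (f + 1) % k
            train = ~(test | val)
            if scale_inputs:
                lo, hi = X[train].min(axis=0), X[train].max(axis=0)
                span = np.where(hi > lo, hi - lo, 1.0)
                Xs = (X - lo) / span
            else:
                Xs = X
            res = evolve((Xs[train], y_enc[train]), (Xs[val], y_enc[val]), config, rng)
            acc = _accuracy(res.best, Xs[test], y_enc[test], classes.size)
            fold_acc[r, f] = acc
            if run_best is None or acc > run_best[0]:
                run_best = (acc, res.best)
        winners.append(run_best[1])
    run_means = fold_acc.mean(axis=1)
    return CrossValResult(
        fold_accuracies=fold_acc,
        run_means=run_means,
        mean_accuracy=float(run_means.mean()),
        sd_accuracy=float(run_means.std(ddof=1)) if runs > 1 else 0.0,
        pooled_mean=float(fold_acc.mean()),
        winners=winners,
    )


# ---------------------------------------------------------------------------
# white-box export

_OPS = {0: "+", 1: "-", 2: "*", 3: "/"}


def export_expression(genotype: CgpGenotype, feature_names: list[str] | None = None) -> dict:
    """Serialize the active subgraph as arithmetic expressions and DOT.

    Returns {"expressions": [str per output], "active_inputs": [names],
    "dot": str}.  Division renders as div(a, b) to keep the protected
    semantics explicit; inactive nodes never appear.
    """
    cfg = genotype.config
    names = feature_names or [f"x{i}" for i in range(cfg.n_inputs)]
    if len(names) != cfg.n_inputs:
        raise ValueError("feature_names length must equal n_inputs")

    cache: dict[int, str] = {}

    def expr(ref: int) -> str:
        if ref < cfg.n_inputs:
            return names[ref]
        if ref in cache:
            return cache[ref]
        node = ref - cfg.n_inputs
        f, c1, c2 = (int(v) for v in genotype.genes[3 * node: 3 * node + 3])
        a, b = expr(c1), expr(c2)
        s = f"div({a}, {b})" if f == 3 else f"({a} {_OPS[f]} {b})"
        cache[ref] = s
        return s

    out_genes = [int(g) for g in genotype.genes[3 * cfg.n_nodes:]]
    expressions = [expr(g) for g in out_genes]

    active = genotype.active_nodes()
    lines = ["digraph cgp {", "  rankdir=LR;"]
    for i in genotype.active_inputs():
        lines.append(f'  in{i} [label="{names[i]}", shape=box];')
    for node in active:
        f, c1, c2 = (int(v) for v in genotype.genes[3 * node: 3 * node + 3])
        lines.append(f'  n{node} [label="{_FUNCTION_NAMES[f]}"];')
        for ref in (c1, c2):
            src = f"in{ref}" if ref < cfg.n_inputs else f"n{ref - cfg.n_inputs}"
            lines.append(f"  {src} -> n{node};")
    for oi, g in enumerate(out_genes):
        src = f"in{g}" if g < cfg.n_inputs else f"n{g - cfg.n_inputs}"
        lines.append(f'  out{oi} [label="out{oi}", shape=doublecircle];')
        lines.append(f"  {src} -> out{oi};")
    lines.append("}")
    return {
        "expressions": expressions,
        "active_inputs": [names[i] for i in genotype.active_inputs()],
        "dot": "\n".join(lines),
    }
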