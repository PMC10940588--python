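"""Train the genetic neural network: a single-hidden-layer perceptron whose
weights are evolved, not backpropagated.

The genetic algorithm minimizes max{MSE_train, MSE_test} (class-weighted),
so a genome only scores well if it fits the training split without losing
the held-out test split.  With elitism the best fitness never rises.
"""

import numpy as np

from sozmark.gnn_classifier import GAConfig, evolve, forward

rng = np.random.default_rng(0)
n = 150
y = rng.integers(0, 2, n)
X = rng.standard_normal((n, 2)) + np.where(y[:, None] == 1, 1.6, -1.6) * np.array([1.0, 0.4])
X_train, y_train, X_test, y_test = X[:120], y[:120], X[120:], y[120:]

cfg = GAConfig(population_size=50, generations=80, seed=1)
genome, history = evolve(cfg, (X_train, y_train), (X_test, y_test))

print(f"genome length {genome.weights.size} "
      f"(10 hidden tanh units on {genome.n_in} inputs, logistic output)")
for h in history[:: len(history) // 8]:
    print(f"  generation {h.generation:3d}  best fitness {h.best_fitness:.4f}  "
          f"mean {h.mean_fitness:.4f}")
acc_tr = np.mean((forward(genome, X_train) > 0.5) == y_train)
acc_te = np.mean((forward(genome, X_test) > 0.5) == y_test)
print(f"training accuracy {acc_tr:.3f}   test accuracy {acc_te:.3f}")
print("fitness is the WORSE of the two splits' errors, so both stay honest")
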