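# Frozen hyperparameters for the selection ensemble (8 members) and the
# held-out validation panel (5 classifiers). Values differing from
# scikit-learn defaults are speed/convergence choices for desk-scale
# tables (a few hundred samples x a few hundred ASVs); they are part of
# the versioned method definition and hashed into `refsig --version`.
ensemble:
  sgd: {}
  svc:
    kernel: linear
  gradient_boosting:
    n_estimators: 50
    max_features: sqrt
  random_forest:
    n_estimators: 50
  logistic_regression:
    max_iter: 1000
  passive_aggressive: {}
  ridge: {}
  bagging: {}
validation:
  adaboost: {}
  extra_trees: {}
  kneighbors: {}
  mlp:
    max_iter: 500
  lassocv: {}
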