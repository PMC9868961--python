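{
  "description": "Published evaluation of the eleven classifier configurations on the curated plant on/off-target dataset: eight metrics per model (percentages) and the multi-criteria closeness scores and ranks reported alongside them. Used as the reference decision matrix for ranking demonstrations and reproduction checks.",
  "metric_names": ["accuracy", "precision", "recall", "fpr", "specificity", "f1", "f2", "auc"],
  "models": {
    "ANN1-Logistic": [91.65, 89.00, 96.49, 14.05, 85.95, 92.59, 94.89, 97.26],
    "ANN2-Logistic": [86.87, 81.78, 97.44, 25.57, 74.43, 88.93, 93.85, 90.54],
    "ANN1-Tanh":     [90.33, 88.29, 94.68, 14.80, 85.20, 91.37, 93.33, 93.18],
    "ANN2-Tanh":     [87.66, 84.23, 94.98, 20.95, 79.05, 89.28, 92.61, 95.34],
    "ANN1-ReLU":     [90.65, 90.44, 92.49, 11.52, 88.48, 91.45, 92.07, 96.94],
    "ANN2-ReLU":     [77.39, 73.50, 91.00, 38.65, 61.35, 81.32, 86.86, 91.20],
    "SVM-Linear":    [87.26, 88.31, 88.10, 13.74, 86.26, 88.21, 88.14, 92.00],
    "SVM-Polynomial":[85.22, 86.15, 86.61, 16.41, 83.59, 86.38, 86.52, 93.51],
    "SVM-Gaussian":  [84.18, 85.88, 84.68, 16.41, 83.59, 85.28, 84.92, 93.45],
    "SVM-Sigmoid":   [54.09, 54.09, 100.00, 100.00, 0.00, 70.21, 85.49, 50.00],
    "RF":            [96.27, 94.75, 98.56, 6.44, 93.56, 96.62, 97.77, 99.21]
  },
  "published_closeness": {
    "RF": 0.961423,
    "ANN1-Logistic": 0.789202,
    "ANN1-ReLU": 0.69774,
    "ANN1-Tanh": 0.602147,
    "ANN2-Tanh": 0.516367,
    "SVM-Linear": 0.482942,
    "ANN2-Logistic": 0.447746,
    "SVM-Polynomial": 0.386691,
    "SVM-Gaussian": 0.327762,
    "SVM-Sigmoid": 0.276047,
    "ANN2-ReLU": 0.166041
  }
}
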