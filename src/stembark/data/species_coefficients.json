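{
  "schema": "stembark-coefficients-v1",
  "notes": "Published regression coefficients for four young broadleaved species. Units: dbh model mm = f(D0 mm); height model m = f(D0 mm); radius model cm = f(D0 mm, Hg cm); thickness model mm = f(D0 mm, Hg cm). p-values are kept exactly as printed (some only as upper bounds).",
  "species": {
    "common_aspen": {
      "dbh": {
        "coefficients": {"b0": -3.422, "b1": 0.763},
        "se": {"b0": 0.911, "b1": 0.022},
        "p": {"b0": "<0.001", "b1": "<0.001"},
        "r_squared": 0.890,
        "mse": 29.46
      },
      "height": {
        "coefficients": {"b0": 8.221, "b1": 7.077, "b2": 0.021},
        "se": {"b0": 11.812, "b1": 0.693, "b2": 0.009},
        "p": {"b0": "0.487", "b1": "<0.001", "b2": "0.017"},
        "r_squared": 0.897,
        "mse": 1218.609
      },
      "radius": {
        "coefficients": {"b0": 0.038, "b1": 1.076, "b2": -0.092},
        "se": {"b0": 0.002, "b1": 0.010, "b2": 0.002},
        "p": {"b0": "<0.001", "b1": "<0.001", "b2": "<0.001"},
        "r_squared": 0.916,
        "mse": 0.057,
        "response_unit": "cm"
      },
      "thickness": {
        "coefficients": {"b0": 0.092, "b1": 0.968, "b2": -0.144},
        "se": {"b0": 0.016, "b1": 0.016, "b2": 0.004},
        "p": {"b0": "<0.001", "b1": "<0.001", "b2": "<0.001"},
        "r_squared": 0.786,
        "mse": 0.287,
        "response_unit": "mm"
      },
      "population": {
        "n_trees": 180,
        "d0_mean_mm": 31.9,
        "d0_sd_mm": 21.1,
        "height_mean_m": 3.84,
        "height_sd_m": 2.45
      }
    },
    "goat_willow": {
      "dbh": {
        "coefficients": {"b0": -5.285, "b1": 0.620},
        "se": {"b0": 0.971, "b1": 0.031},
        "p": {"b0": "<0.001", "b1": "<0.001"},
        "r_squared": 0.838,
        "mse": 11.60
      },
      "height": {
        "coefficients": {"b0": 6.921, "b1": 8.127, "b2": 0.126},
        "se": {"b0": 4.691, "b1": 0.542, "b2": 0.016},
        "p": {"b0": "0.143", "b1": "<0.001", "b2": "<0.001"},
        "r_squared": 0.812,
        "mse": 237.939
      },
      "radius": {
        "coefficients": {"b0": 0.088, "b1": 0.847, "b2": -0.179},
        "se": {"b0": 0.010, "b1": 0.034, "b2": 0.007},
        "p": {"b0": "<0.001", "b1": "<0.001", "b2": "<0.001"},
        "r_squared": 0.594,
        "mse": 0.107,
        "response_unit": "cm"
      },
      "thickness": {
        "coefficients": {"b0": 0.129, "b1": 0.784, "b2": -0.145},
        "se": {"b0": 0.010, "b1": 0.023, "b2": 0.004},
        "p": {"b0": "<0.001", "b1": "<0.001", "b2": "<0.001"},
        "r_squared": 0.671,
        "mse": 0.097,
        "response_unit": "mm"
      },
      "population": {
        "n_trees": 120,
        "d0_mean_mm": 25.0,
        "d0_sd_mm": 13.2,
        "height_mean_m": 2.04,
        "height_sd_m": 0.85
      }
    },
    "rowan": {
      "dbh": {
        "coefficients": {"b0": -3.629, "b1": 0.665},
        "se": {"b0": 0.711, "b1": 0.016},
        "p": {"b0": "<0.001", "b1": "<0.001"},
        "r_squared": 0.958,
        "mse": 7.83
      },
      "height": {
        "coefficients": {"b0": 14.640, "b1": 6.486, "b2": 0.135},
        "se": {"b0": 13.260, "b1": 0.969, "b2": 0.014},
        "p": {"b0": "0.273", "b1": "<0.001", "b2": "<0.001"},
        "r_squared": 0.933,
        "mse": 287.626
      },
      "radius": {
        "coefficients": {"b0": 0.045, "b1": 1.038, "b2": -0.139},
        "se": {"b0": 0.004, "b1": 0.020, "b2": 0.003},
        "p": {"b0": "<0.001", "b1": "<0.001", "b2": "<0.001"},
        "r_squared": 0.886,
        "mse": 0.075,
        "response_unit": "cm"
      },
      "thickness": {
        "coefficients": {"b0": 0.160, "b1": 0.620, "b2": -0.055},
        "se": {"b0": 0.011, "b1": 0.018, "b2": 0.005},
        "p": {"b0": "<0.001", "b1": "<0.001", "b2": "<0.001"},
        "r_squared": 0.681,
        "mse": 0.089,
        "response_unit": "mm"
      },
      "population": {
        "n_trees": 100,
        "d0_mean_mm": 36.7,
        "d0_sd_mm": 21.4,
        "height_mean_m": 2.82,
        "height_sd_m": 1.21
      }
    },
    "sycamore": {
      "dbh": {
        "coefficients": {"b0": -4.948, "b1": 0.718},
        "se": {"b0": 0.732, "b1": 0.017},
        "p": {"b0": "<0.001", "b1": "<0.001"},
        "r_squared": 0.950,
        "mse": 12.38
      },
      "height": {
        "coefficients": {"b0": 84.237, "b1": 3.273, "b2": 0.073},
        "se": {"b0": 25.897, "b1": 1.311, "b2": 0.014},
        "p": {"b0": "0.001", "b1": "0.014", "b2": "<0.001"},
        "r_squared": 0.882,
        "mse": 723.968
      },
      "radius": {
        "coefficients": {"b0": 0.036, "b1": 1.079, "b2": -0.110},
        "se": {"b0": 0.002, "b1": 0.014, "b2": 0.004},
        "p": {"b0": "<0.001", "b1": "<0.001", "b2": "<0.003"},
        "r_squared": 0.851,
        "mse": 0.089,
        "response_unit": "cm"
      },
      "thickness": {
        "coefficients": {"b0": 0.098, "b1": 0.659, "b2": -0.072},
        "se": {"b0": 0.006, "b1": 0.016, "b2": 0.005},
        "p": {"b0": "<0.001", "b1": "<0.001", "b2": "<0.001"},
        "r_squared": 0.587,
        "mse": 0.059,
        "response_unit": "mm"
      },
      "population": {
        "n_trees": 200,
        "d0_mean_mm": 25.8,
        "d0_sd_mm": 13.2,
        "height_mean_m": 2.85,
        "height_sd_m": 2.30
      }
    }
  }
}
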