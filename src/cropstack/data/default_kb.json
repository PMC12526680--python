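{
  "comment": "Illustrative per-crop optima (mean/sd of ideal temperature in degrees C and soil pH). Shipped so the pipeline runs out of the box; replace with a curated agronomic table for real analyses.",
  "crops": [
    {"label": "apple",       "mu_temp": 21.0, "sigma_temp": 2.0, "mu_ph": 6.0, "sigma_ph": 0.40},
    {"label": "banana",      "mu_temp": 27.0, "sigma_temp": 2.5, "mu_ph": 6.2, "sigma_ph": 0.45},
    {"label": "blackgram",   "mu_temp": 29.5, "sigma_temp": 2.5, "mu_ph": 7.1, "sigma_ph": 0.40},
    {"label": "chickpea",    "mu_temp": 18.5, "sigma_temp": 2.0, "mu_ph": 7.3, "sigma_ph": 0.35},
    {"label": "coconut",     "mu_temp": 27.0, "sigma_temp": 1.5, "mu_ph": 5.9, "sigma_ph": 0.35},
    {"label": "coffee",      "mu_temp": 23.5, "sigma_temp": 2.0, "mu_ph": 6.8, "sigma_ph": 0.35},
    {"label": "cotton",      "mu_temp": 24.0, "sigma_temp": 2.0, "mu_ph": 6.9, "sigma_ph": 0.30},
    {"label": "grapes",      "mu_temp": 23.0, "sigma_temp": 4.0, "mu_ph": 6.0, "sigma_ph": 0.45},
    {"label": "jute",        "mu_temp": 25.0, "sigma_temp": 1.5, "mu_ph": 6.7, "sigma_ph": 0.35},
    {"label": "kidneybeans", "mu_temp": 20.0, "sigma_temp": 1.8, "mu_ph": 5.8, "sigma_ph": 0.30},
    {"label": "lentil",      "mu_temp": 24.5, "sigma_temp": 2.0, "mu_ph": 6.9, "sigma_ph": 0.35},
    {"label": "maize",       "mu_temp": 22.5, "sigma_temp": 2.2, "mu_ph": 6.2, "sigma_ph": 0.35},
    {"label": "mango",       "mu_temp": 31.0, "sigma_temp": 2.0, "mu_ph": 5.8, "sigma_ph": 0.40},
    {"label": "mothbeans",   "mu_temp": 28.5, "sigma_temp": 3.0, "mu_ph": 6.8, "sigma_ph": 0.55},
    {"label": "mungbean",    "mu_temp": 28.5, "sigma_temp": 1.8, "mu_ph": 6.7, "sigma_ph": 0.30},
    {"label": "muskmelon",   "mu_temp": 28.7, "sigma_temp": 1.2, "mu_ph": 6.4, "sigma_ph": 0.25},
    {"label": "orange",      "mu_temp": 22.8, "sigma_temp": 1.8, "mu_ph": 7.0, "sigma_ph": 0.30},
    {"label": "papaya",      "mu_temp": 33.5, "sigma_temp": 2.5, "mu_ph": 6.7, "sigma_ph": 0.30},
    {"label": "pigeonpeas",  "mu_temp": 27.7, "sigma_temp": 3.0, "mu_ph": 5.8, "sigma_ph": 0.45},
    {"label": "pomegranate", "mu_temp": 21.8, "sigma_temp": 1.8, "mu_ph": 6.4, "sigma_ph": 0.30},
    {"label": "rice",        "mu_temp": 23.7, "sigma_temp": 1.5, "mu_ph": 6.4, "sigma_ph": 0.35},
    {"label": "watermelon",  "mu_temp": 25.6, "sigma_temp": 1.2, "mu_ph": 6.5, "sigma_ph": 0.25}
  ]
}
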