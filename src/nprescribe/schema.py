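"""Column layout of a field table.

A field table is a plain CSV with one row per sampled site/season. Covariates
fall into four groups — weather/climate forcing, soil/terrain structure,
in-season crop-condition indices, and management/categorical identifiers —
plus the yield target and the applied nitrogen rate.
"""

TARGET = "Yield"
RATE = "N"  # applied nitrogen rate proxy, kg/ha

WEATHER = [
    "Temperature",
    "Humidity",
    "Rainfall",
    "SolarRadiation",
    "WindSpeed",
    "GrowingDegreeDays",
]

SOIL_CATEGORICAL = ["SoilType"]
SOIL_NUMERIC = [
    "pH",
    "ElectricalConductivity",
    "OrganicCarbon",
    "CationExchangeCapacity",
    "Sand",
    "Silt",
    "Clay",
    "BulkDensity",
    "WaterHoldingCapacity",
    "Slope",
    "Aspect",
    "Elevation",
]

CROP_CONDITION = ["NDVI", "EVI", "LAI", "Chlorophyll"]

MANAGEMENT_CATEGORICAL = [
    "CropType",
    "GrowthStage",
    "FertilizerType",
    "PesticideUsage",
    "Region",
    "Season",
]
MANAGEMENT_NUMERIC = ["IrrigationFrequency", "Year"]
DATE_COLUMNS = ["PlantingDate", "HarvestDate"]

# season-timing features derived from the date columns at transform time
DERIVED_TIME = ["SeasonLengthDays", "PlantingDayOfYear"]

NUMERIC_COVARIATES = WEATHER + SOIL_NUMERIC + CROP_CONDITION + MANAGEMENT_NUMERIC
CATEGORICAL_COVARIATES = SOIL_CATEGORICAL + MANAGEMENT_CATEGORICAL
COVARIATES = NUMERIC_COVARIATES + CATEGORICAL_COVARIATES + DATE_COLUMNS

ALL_COLUMNS = (
    [TARGET, RATE]
    + WEATHER
    + SOIL_CATEGORICAL
    + SOIL_NUMERIC
    + CROP_CONDITION
    + MANAGEMENT_CATEGORICAL
    + MANAGEMENT_NUMERIC
    + DATE_COLUMNS
)

# fields forming the leakage-free grouping key (region x crop x year x season)
GROUP_FIELDS = ["Region", "CropType", "Year", "Season"]

# feature-group ablation variants: base (pre-encoding) column names per group
FEATURE_GROUPS = {
    "weather": list(WEATHER),
    "soil": SOIL_CATEGORICAL + SOIL_NUMERIC,
    "crop_indices": list(CROP_CONDITION),
    "management": MANAGEMENT_CATEGORICAL + MANAGEMENT_NUMERIC + DERIVED_TIME,
}
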