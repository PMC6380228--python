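# Editable concept-group fixture: concept <TAB> member attribute name.
# Groups of syntactically different attribute names seemingly used for the
# same aspect of a sample; used for per-concept record counting. Groups must
# be disjoint.
Geographic location	latitude and longtitude
Geographic location	lat_lon
Geographic location	Lat-Long
Geographic location	geo_loc
Geographic location	lat_lan
Geographic location	lat_lo
Geographic location	lat_lon (N:W)
Geographic location	lat_lon_2
Geographic location	lat_long
Geographic location	latitude_longitude
Geographic location	geographic location (latitude and longitude)
Geographic location	geographic_location
Height	height or length
Height	height cm
Height	Height..cm.
Height	height
Height	Height
Height	height (cm)
Height	height in
Height	Height (m)
Height	height m
Height	height_cm
Height	height_m
Height	height_meters
Height	Height in Centimeters
Height	height_meter
Elevation	elevation
Elevation	elev
Elevation	elevation(m)
Elevation	Elevation m
Elevation	elevation meters
Elevation	gps elevation
Elevation	geographic location (altitude/elevation)
Elevation	geographic location (elevation)
Elevation	estimated elevation
Age	age
Age	age in years
Age	age (in years)
Age	Age(years)
Age	age_in_years
Age	age years
Age	age (years)
Age	age(years)
Age	age_years
Age	age (yr)
Age	age (yrs)
Age	age in days
Age	age_days
Age	Age(days)
Age	AgeDays
Age	age (days)
Age	age in weeks
Age	age (weeks)
Weight	total_mass
Weight	weight kg
Weight	Weight..kg.
Weight	weight (kg)
Weight	weight_kg
Weight	weight
Weight	Weight_lb
Weight	weight lbs
Weight	weight_pounds
Weight	weight_g
Weight	Weight (g)
Weight	weight_in_grams
Weight	Weight (mg)
Birth date	birth_date
Birth date	date of birth
Birth date	Date of birth
Birth date	date_of_birth
Birth date	year of birth
Birth date	year_of_birth
Birth date	birthyear
Birth date	birth_year
Birth date	year born
Birth date	birth year
Time point	Timepoint
Time point	Time.point
Time point	time point
Time point	time points
Time point	time-point
Time point	time_point
Time point	Timepoints
Time point	time-point in minutes
Time point	timepoint in minutes
Time point	time-window
Time point	time
Time point	time_period
Time point	time period
Time point	time_point_days
Time point	time_point_months
Country or Region	geographic location
Country or Region	country region
Country or Region	CountryOrRegion
Country or Region	country location
Country or Region	country nation
Country or Region	country of origin
Country or Region	geographic location (country and/or sea)
Country or Region	geographic location (country and/or sea, region)
Country or Region	geographic location country 2
Collection date/time	collection_date
Collection date/time	collectiontime
Collection date/time	collected date
Collection date/time	collection_date (dmy)
Collection date/time	collection day
Collection date/time	collection month
Collection date/time	collection date unformat
Collection date/time	collection time
Collection date/time	collection timestamp
Ethnicity	ethinicity
Ethnicity	ethinity
Ethnicity	raceethnicity
Ethnicity	ethnicity
Sample type	sample_type
Sample type	sample type
Sample type	sample-type
Sample type	type of sample
Sample type	type_sample
Sample type	sample_ type
Sample type	type sample
Sample type	type_of_sample
Sample type	sample type description
Sample type	sample_type_beta
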