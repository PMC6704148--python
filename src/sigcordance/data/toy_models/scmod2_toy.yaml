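# TOY module-score subtyping model (SCMOD2-style decision tree over
# ER/HER2/proliferation module scores). NON-CLINICAL toy cutpoints.
name: scmod2_toy
family: module_subtype
centering: reference_set
modules:
  er:
    - ER001
    - ER002
    - ER003
    - ER004
    - ER005
    - ER006
    - ER007
    - ER008
    - ER009
    - ER010
    - ER011
    - ER012
    - ER013
    - ER014
    - ER015
    - ER016
    - ER017
    - ER018
    - ER019
    - ER020
  her2:
    - HER2001
    - HER2002
    - HER2003
    - HER2004
    - HER2005
    - HER2006
    - HER2007
    - HER2008
    - HER2009
    - HER2010
    - HER2011
    - HER2012
    - HER2013
    - HER2014
    - HER2015
  proliferation:
    - PROL001
    - PROL002
    - PROL003
    - PROL004
    - PROL005
    - PROL006
    - PROL007
    - PROL008
    - PROL009
    - PROL010
    - PROL011
    - PROL012
    - PROL013
    - PROL014
    - PROL015
    - PROL016
    - PROL017
    - PROL018
    - PROL019
    - PROL020
cuts: {er: 0.0, her2: 1.0, proliferation: 0.5}
classes:
  her2: HER2-like
  luminal_low: LumA-like
  luminal_high: LumB-like
  basal: Basal-like
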