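<?xml version="1.0" encoding="UTF-8"?>
<!-- Exchange schema for preprocessed MRS data.

     A DATASET holds exactly one Preprocessing history and exactly one
     payload: a Voxel (single-voxel) or a Grid of Voxels (multi-voxel).
     Step elements are optional and ordered; absence of a step element
     means the step was not performed.  Only AdditionalInformation with
     its Name and Place children is always required.  The schema has no
     fields for patient identifiers: output is anonymized by construction.
-->
<xs:schema xmlns:xs="http://www.w3.org/2001/XMLSchema" elementFormDefault="qualified">

  <xs:simpleType name="NonEmptyString">
    <xs:restriction base="xs:string">
      <xs:minLength value="1"/>
    </xs:restriction>
  </xs:simpleType>

  <xs:simpleType name="KeywordString">
    <xs:restriction base="xs:string">
      <xs:maxLength value="45"/>
    </xs:restriction>
  </xs:simpleType>

  <xs:simpleType name="ApodizeShape">
    <xs:restriction base="xs:string">
      <xs:enumeration value="Gaussian"/>
      <xs:enumeration value="Lorentzian"/>
    </xs:restriction>
  </xs:simpleType>

  <xs:simpleType name="StorageKind">
    <xs:restriction base="xs:string">
      <xs:enumeration value="complex"/>
      <xs:enumeration value="real"/>
    </xs:restriction>
  </xs:simpleType>

  <xs:complexType name="RegionType">
    <xs:attribute name="upper" type="xs:double" use="required"/>
    <xs:attribute name="lower" type="xs:double" use="required"/>
  </xs:complexType>

  <xs:complexType name="SetReferenceType">
    <xs:attribute name="reference_ppm" type="xs:double" use="required"/>
  </xs:complexType>

  <xs:complexType name="ApodizeType">
    <xs:attribute name="shape" type="ApodizeShape" use="required"/>
    <xs:attribute name="linewidth_hz" type="xs:double" use="required"/>
  </xs:complexType>

  <xs:complexType name="WaterFilteringType">
    <xs:sequence>
      <xs:element name="Region" type="RegionType" minOccurs="1" maxOccurs="3"/>
    </xs:sequence>
    <xs:attribute name="n_lorentzians" type="xs:positiveInteger" use="required"/>
  </xs:complexType>

  <xs:complexType name="BaselineCorrectionType">
    <xs:sequence>
      <xs:element name="Region" type="RegionType" minOccurs="1" maxOccurs="3"/>
    </xs:sequence>
  </xs:complexType>

  <xs:complexType name="ChangePointsType">
    <xs:sequence>
      <xs:element name="Region" type="RegionType"/>
    </xs:sequence>
    <xs:attribute name="target_points" type="xs:positiveInteger" use="required"/>
  </xs:complexType>

  <xs:complexType name="SetToZeroType">
    <xs:sequence>
      <xs:element name="Region" type="RegionType" minOccurs="1" maxOccurs="2"/>
    </xs:sequence>
  </xs:complexType>

  <xs:complexType name="NormalizationType">
    <xs:attribute name="norm" type="xs:string" fixed="l2"/>
  </xs:complexType>

  <xs:complexType name="AlignmentCorrectionType">
    <xs:sequence>
      <xs:element name="Peak" type="xs:double" minOccurs="1" maxOccurs="unbounded"/>
      <xs:element name="NoiseRegion" type="RegionType"/>
    </xs:sequence>
    <xs:attribute name="max_shift" type="xs:positiveInteger" use="required"/>
  </xs:complexType>

  <xs:complexType name="OutputRangeType">
    <xs:sequence>
      <xs:element name="Region" type="RegionType"/>
    </xs:sequence>
  </xs:complexType>

  <xs:complexType name="AdditionalInformationType">
    <xs:sequence>
      <xs:element name="Name" type="NonEmptyString"/>
      <xs:element name="Place" type="NonEmptyString"/>
      <xs:element name="Date" type="xs:date" minOccurs="0"/>
      <xs:element name="Label" type="xs:string" minOccurs="0"/>
      <xs:element name="Keywords" minOccurs="0">
        <xs:complexType>
          <xs:sequence>
            <xs:element name="Keyword" type="KeywordString" minOccurs="0" maxOccurs="unbounded"/>
          </xs:sequence>
        </xs:complexType>
      </xs:element>
      <xs:element name="MetaData" type="xs:string" minOccurs="0"/>
    </xs:sequence>
    <xs:attribute name="include_snr" type="xs:boolean" use="optional"/>
  </xs:complexType>

  <xs:complexType name="PreprocessingType">
    <xs:sequence>
      <xs:element name="SetReference" type="SetReferenceType" minOccurs="0"/>
      <xs:element name="Apodize" type="ApodizeType" minOccurs="0"/>
      <xs:element name="WaterFiltering" type="WaterFilteringType" minOccurs="0"/>
      <xs:element name="BaselineCorrection" type="BaselineCorrectionType" minOccurs="0"/>
      <xs:element name="ChangePoints" type="ChangePointsType" minOccurs="0"/>
      <xs:element name="SetToZero" type="SetToZeroType" minOccurs="0"/>
      <xs:element name="Normalization" type="NormalizationType" minOccurs="0"/>
      <xs:element name="AlignmentCorrection" type="AlignmentCorrectionType" minOccurs="0"/>
      <xs:element name="OutputRange" type="OutputRangeType" minOccurs="0"/>
      <xs:element name="AdditionalInformation" type="AdditionalInformationType"/>
    </xs:sequence>
  </xs:complexType>

  <xs:complexType name="SnrType">
    <xs:attribute name="value" type="xs:double" use="required"/>
    <xs:attribute name="max_peak" type="xs:double" use="required"/>
    <xs:attribute name="noise_std" type="xs:double" use="required"/>
  </xs:complexType>

  <xs:complexType name="VoxelType">
    <xs:sequence>
      <xs:element name="SNR" type="SnrType" minOccurs="0"/>
      <xs:element name="Data" type="xs:string"/>
    </xs:sequence>
    <xs:attribute name="points" type="xs:positiveInteger" use="required"/>
    <xs:attribute name="ppm_first" type="xs:double" use="required"/>
    <xs:attribute name="ppm_step" type="xs:double" use="required"/>
    <xs:attribute name="transmitter_frequency" type="xs:double" use="required"/>
    <xs:attribute name="sweep_width" type="xs:double" use="required"/>
    <xs:attribute name="acq_points" type="xs:positiveInteger" use="required"/>
    <xs:attribute name="reference_ppm" type="xs:double" use="required"/>
    <xs:attribute name="nucleus" type="xs:string" use="optional"/>
    <xs:attribute name="storage" type="StorageKind" use="required"/>
    <xs:attribute name="label" type="xs:string" use="optional"/>
  </xs:complexType>

  <xs:complexType name="GridVoxelType">
    <xs:complexContent>
      <xs:extension base="VoxelType">
        <xs:attribute name="Xaxis" type="xs:positiveInteger" use="required"/>
        <xs:attribute name="Yaxis" type="xs:positiveInteger" use="required"/>
        <xs:attribute name="Zaxis" type="xs:positiveInteger" use="required" fixed="1"/>
      </xs:extension>
    </xs:complexContent>
  </xs:complexType>

  <xs:complexType name="GridType">
    <xs:sequence>
      <xs:element name="Voxel" type="GridVoxelType" minOccurs="1" maxOccurs="unbounded"/>
    </xs:sequence>
    <xs:attribute name="rows" type="xs:positiveInteger" use="required"/>
    <xs:attribute name="cols" type="xs:positiveInteger" use="required"/>
  </xs:complexType>

  <xs:element name="DATASET">
    <xs:complexType>
      <xs:sequence>
        <xs:element name="Preprocessing" type="PreprocessingType"/>
        <xs:choice>
          <xs:element name="Voxel" type="VoxelType"/>
          <xs:element name="Grid" type="GridType"/>
        </xs:choice>
      </xs:sequence>
    </xs:complexType>
  </xs:element>

</xs:schema>
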